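# licklab

Operant-licking experiments train a rodent to lick a drinking spout for a
fluid reward delivered under a reinforcement schedule — fixed ratio (FR),
variable ratio (VR), or progressive ratio (PR) — while a lickometer records
every tongue contact with millisecond timing. `licklab` is a pure-software
implementation of such a system for behavioral neuroscientists and tool
builders: the schedule engines and session controller that turn a raw,
RFID-started event stream into a complete session log; a seeded virtual-rat
simulator that stands in for the animal and the hardware; the standard
lick-microstructure analysis; and a pipeline for the environmental logs
(temperature, humidity, pressure, illuminance) that accompany such studies.

## The model in brief

A session starts when the subject's implanted RFID tag (a 12-hex-character
identifier) is scanned. Licks on the *active* spout drive the schedule;
licks on the *inactive* spout are logged only. Under FR *n* every *n*
counted licks earn a reward; under VR *n* the requirement is redrawn after
each reward, uniform on {1, …, 2n−1} (mean exactly *n*); under PR the
requirement for the k-th reward is `base + (k−1)·step`. Each reward opens a
20 s timeout — licks are recorded but not counted — and lights a cue for
5 s. FR/VR sessions last one hour; PR sessions end 10 min after the last
active-spout lick, and the number of rewards earned (the *break point*)
indexes motivation.

The analysis side implements lick microstructure: licks within 0.5 s of
each other form a *cluster* (clusters of fewer than two licks are
excluded); cluster size tracks the palatability of the fluid, and the
within-cluster inter-lick interval (ILI) is a stereotyped ~0.15 s in the
rat. Group comparisons of active- vs inactive-spout counts use the
two-sample pooled-variance Student's t-test.

See `docs/methods.md` for the full model, parameter table, and design
choices.

## Worked example

Simulate a sucrose-avid virtual rat, run it through an FR10 session, and
analyze the log:

```python
import licklab as L

stream = L.simulate_rat(L.sucrose_like(), rng=1)
spec = L.ScheduleSpec("FR", ratio=10)          # FR10, 20 s timeout, 5 s cue, 1 h
record = L.run_session(stream, spec, seed=1)

counts = L.session_summary(record)
print(f"active licks:   {counts.licks_active}")
print(f"inactive licks: {counts.licks_inactive}")
print(f"rewards:        {counts.rewards}")

micro = L.record_microstructure(record)["active"]
print(f"clusters:       {micro.n_clusters}")
print(f"cluster size:   {micro.mean_cluster_size:.1f} ± {micro.sem_cluster_size:.1f}")
print(f"ILI:            {micro.mean_ili_s:.3f} ± {micro.sem_ili_s:.3f} s")
```

prints

```
active licks:   5406
inactive licks: 215
rewards:        88
clusters:       141
cluster size:   38.3 ± 3.3
ILI:            0.150 ± 0.000 s
```

— a strongly active-preferring rat licking ~5.4k times in the hour, earning
88 drops (one per 10 counted licks, throttled by the 20 s timeout), in
large bursts (~38 licks) at the stereotyped ~6.7 Hz lick rate. The same
pipeline is available from the shell:

```sh
licklab simulate --schedule fr10 --preset sucrose --seed 1 --out out/
licklab analyze --log out/session_*.csv --out analysis/
licklab env-simulate --days 7 --seed 1 --changepoint-day 4 --out env.csv
licklab env-analyze --series env.csv --out env_analysis/
```

Session logs are plain CSV (`time_s,kind,tag`) with a commented sidecar
carrying the subject tag, schedule parameters, and seed; identical seeds
reproduce every output byte-for-byte.

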