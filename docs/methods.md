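# Methods

`licklab` is a pure-software counterpart of an RFID-started operant
lickometer for rats: the reinforcement-schedule logic, the session
controller, a generative stand-in for the animal, the lick-microstructure
analysis, and the environmental-log pipeline. This note records the models,
the parameters that matter, and the design choices made where the design was
genuinely open.

## Session model and schedule semantics

A session is a time-ordered event stream. The clock starts at the RFID scan
of the subject's implanted glass tag (a 12-hex-character identifier); licks
on the **active** spout drive the schedule, licks on the **inactive** spout
are recorded but have no programmed consequence, and motion-sensor events
are logged alongside.

Three schedule families share one state machine
(`licks_toward_requirement`, `current_requirement`, `rewards_delivered`,
timeout/cue windows):

- **FR n** — reward after every n counted licks.
- **VR n** — the requirement is redrawn after each reward, uniformly on
  {1, …, 2n−1}. The family of the draw distribution is a design choice (only
  the mean is externally constrained); the discrete uniform keeps the mean
  exactly n, bounds the support, and never requires fewer than one lick. A
  fixed requirement cycle (`ScheduleSpec.vr_values`) is available for
  deterministic replays; a one-element cycle makes VR reduce exactly to FR.
  Draw protocol (part of the engine contract): one draw at state
  initialisation, one immediately after each reward.
- **PR** — requirement for the k-th reward is `ratio + (k−1)·pr_step`
  (arithmetic progression, defaults 10 and 5, both configurable). The
  progression rule itself is a design choice; arithmetic is the simplest
  strictly increasing family and both constants are surfaced in config.

**Timeout.** Each reward opens a half-open window `[t, t + timeout_s)`
(default 20 s) during which licks are logged but not counted; a lick landing
exactly at the window's end counts. The reward-triggering lick is included
in its requirement; the counter resets to zero immediately after reward.

**Cue light.** Each reward lights the cue for `cue_s` (default 5 s). Cue and
timeout windows run concurrently and independently; a cue still burning at
session end is closed by a `cue_off` at the end time. In the degenerate case
of a reward arriving while a cue is still on (possible only when
`cue_s > timeout_s`), the open cue is closed at the new reward time.

**Termination.** FR/VR sessions cover the half-open interval
`[0, session_s)` (default 1 h); input at or beyond the end is discarded, not
buffered. PR sessions end `pr_idle_stop_s` (default 600 s) after the last
active-spout lick, evaluated over the whole input stream; with no licks at
all, `pr_idle_stop_s` after the scan.

**Schedule selection.** An `RfidScheduleMap` resolves the scanned tag to a
schedule; unmapped tags fall back to the default, VR 10, mirroring how the
hardware devices select schedules by scanning designated tags. Lookup is
case-insensitive; several tags may map to one schedule.

## Event-log format

No on-disk schema is externally fixed, so this package defines one: a CSV
(`time_s,kind,tag`) with a `#`-prefixed sidecar carrying the subject tag,
every schedule parameter, the seed, and absolute start/end times. Times are
seconds since session start, written as the shortest decimal text that
parses back to the identical float (padded to ≥ 3 fractional digits; licks
are ~0.15 s apart, so millisecond resolution matters). Round-tripping is
exact by construction, equal timestamps are legal, and their input order is
preserved — both properties are tested, including on 10,000-event
randomized logs.

## Virtual rat

The generator is a renewal process over lick clusters, emulating the
empirical structure of rodent licking (stereotyped ~6–7 Hz licking within
bursts, long pauses between bursts, spout preference):

| parameter | sucrose-like | water-like | role |
|---|---|---|---|
| `ili_mean_s` / `ili_sd_s` | 0.15 / 0.02 s | 0.22 / 0.03 s | within-cluster inter-lick interval (truncated normal on (0, 0.5) s) |
| `cluster_size_mean` | 35.7 | 7.2 | shifted geometric, minimum 2 |
| `inter_cluster_gap_mean_s` | 20 s | 180 s | exponential, left-truncated at 0.5 s |
| `active_preference` | 0.95 | 0.75 | per-cluster Bernoulli spout choice |
| `motion_rate_per_min` | 2 | 1 | Poisson motion events |

The ILI means and cluster-size means of the presets are the reported
statistics of real rats licking for 10% sucrose versus water; the
inter-cluster gap has no published counterpart and was calibrated once so a
1-hour simulated session lands near the reported per-session totals (~4.9k
active licks sucrose, ~10² water). Distribution families are chosen for
tractability — only moments are externally constrained.

Two numerical choices matter. Cluster sizes use a shifted geometric
(`size = 1 + Geom(p)`, `p = 1/(mean−1)`) so the minimum is 2 — the smallest
cluster the ≥2-lick analysis rule can detect — with the mean exact. Gaps use
an exponential left-truncated at the 0.5 s cluster threshold (by
memorylessness, `0.5 + Exp` with the rate set so the total mean equals the
parameter): an untruncated exponential would place mass below the threshold
and silently merge generated clusters, biasing parameter recovery; the
truncation makes generated clusters identifiable by the segmentation.

Licking is open-loop — real rats keep licking through the 20 s post-reward
timeout, so no reward feedback is modelled by default; a `suppress` hook
allows closed-loop experiments.

**What passing tests do and do not show.** The simulator reproduces the
clustered timing, spout preference, and palatability contrast of real data;
it does not model satiation within sessions, learning across sessions,
per-spout differences in cluster size, or sensor artefacts (missed or
doubled touches). Parameter-recovery results therefore demonstrate the
correctness of the analysis code on data of known structure, not analytical
performance on in vivo recordings.

## Microstructure analysis

Clusters are maximal runs of licks with consecutive gaps strictly below
0.5 s; runs of one lick are excluded. "Within 0.5 s" is read as strict
(`< 0.5` joins, `= 0.5` splits); the threshold is a parameter. Spouts are
segmented independently — a lick on the other spout does not break a
cluster. ILIs are pooled across clusters for the grand mean (matching the
convention of one reported ILI per condition); per-cluster averaging is
available (`per_cluster=True`), since for sparse inactive-spout licking the
two conventions genuinely differ. Segmentation is exactly conservative:
`Σ cluster sizes + excluded single-lick runs = total licks`.

Group comparisons of active- versus inactive-spout counts use the
two-sample **pooled-variance** Student's t-test (two-sided) — Student's, not
Welch's, because that is the named convention this workflow follows — with
the usual star labels (\* p<0.05, \*\* p<0.01, \*\*\* p<0.001).

## Environmental pipeline

Series are 10-min samples (144/day) of temperature (°C), relative humidity
(%), barometric pressure (kPa), and illuminance (lux). The simulator
produces a reverse light cycle (lights off 09:00, on 21:00), optional
single-sample lux spikes during the dark phase (technician entries), an
optional step in temperature/humidity at a configurable day (defaults −1 °C,
+3%, emulating an HVAC adjustment), and Gaussian sensor noise per channel.

- **Device comparison**: paired a−b differences per variable over samples
  matched by nearest timestamp within 5 min (half the cadence); mean ± sd
  (ddof 1) and n. Antisymmetric by construction.
- **Light transitions**: threshold crossings of the lux trace with a
  2-sample debounce (a transition needs ≥ 2 consecutive samples on the new
  side, timestamped at the first). The default threshold is the midpoint of
  the 5th and 95th lux percentiles — the sensor is treated as uncalibrated,
  only the on/off cycle is meaningful.
- **Step estimation**: least-squares single-changepoint fit (minimum-SSE
  two-segment split, ≥ 6 samples per side), or a plain difference of means
  when the changepoint time is known. Recovery of injected steps within 3×
  the noise sd at 144 samples/day is part of the acceptance suite.

## Determinism and problem sizes

Every stochastic component takes a `numpy` `Generator` or integer seed, and
seeds are recorded in output sidecars, so any pipeline stage reruns
byte-identically. The test suite checks engine/segmentation agreement with
independently coded references on 1,000 seeded streams of 10–10,000 licks;
parameter recovery uses 20 virtual rats at 4-h sessions (≈20k licks each),
a problem size at which per-rat sampling error of the cluster-size mean
(sd ≈ mean for a geometric) is comfortably inside the 5% recovery band.

## Known limitations

- The VR draw distribution and PR progression are explicit choices; systems
  using different conventions will produce different reward sequences even
  at equal means.
- `compare_devices` aligns by nearest timestamp only; it does not resample
  or interpolate irregular series.
- The changepoint estimator fits a single mean shift; drifting baselines or
  multiple shifts need a richer model.
- Temperature is one value per sample; averaging of redundant sensors is
  assumed to happen upstream of the log format.
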