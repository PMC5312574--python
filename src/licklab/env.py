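"""Environmental-log model: simulation, device comparison, light-cycle analysis.

An environmental logger samples temperature (°C), relative humidity (%),
barometric pressure (kPa) and illuminance (lux) once every 10 minutes (144
samples/day). Series are pandas DataFrames with columns ``time``,
``temperature_c``, ``humidity_pct``, ``pressure_kpa``, ``lux``; the CSV
format is ``time_iso,temperature_c,humidity_pct,pressure_kpa,lux``.

Three analyses are provided:

* :func:`compare_devices` — paired per-variable differences between two
  co-located loggers (mean ± sd over samples aligned by nearest timestamp);
* :func:`detect_light_transitions` — lights-on/off events from the lux
  trace by threshold crossing with a debounce, robust to brief spikes from
  technicians entering the room (lux is used only to monitor the light
  cycle, never as a calibrated photometric quantity);
* :func:`estimate_step` — size and location of a step change in one
  variable (e.g. a ~-1 °C temperature shift after an airflow adjustment),
  by least-squares single-changepoint fit or at a known time.

The simulator emulates a tightly climate-controlled animal housing room on
a reverse light cycle (lights off 09:00, on 21:00), with optional lux
spikes (technician entries) and a step change in temperature/humidity at a
configurable changepoint.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime, timedelta
from pathlib import Path
from typing import IO, Union

import numpy as np
import pandas as pd

from .errors import AlignmentError, DomainError

__all__ = [
    "ENV_COLUMNS",
    "EnvParams",
    "simulate_env",
    "read_env_csv",
    "write_env_csv",
    "compare_devices",
    "detect_light_transitions",
    "estimate_step",
    "SAMPLES_PER_DAY",
]

ENV_COLUMNS = ["time", "temperature_c", "humidity_pct", "pressure_kpa", "lux"]
SAMPLE_INTERVAL_MIN = 10
SAMPLES_PER_DAY = 24 * 60 // SAMPLE_INTERVAL_MIN  # 144


@dataclass(frozen=True)
class EnvParams:
    """Baseline levels, light-cycle clock times, and sensor noise SDs.

    The default light cycle is reversed (dark phase during the working day):
    lights off at 09:00, on at 21:00. ``changepoint_day``, when set, applies
    ``temperature_step_c`` and ``humidity_step_pct`` from midnight of that
    day index onward (emulating an HVAC adjustment).
    """

    temperature_c: float = 22.5
    humidity_pct: float = 45.0
    pressure_kpa: float = 101.3
    lux_on: float = 400.0
    lux_off: float = 0.0
    lights_off_hour: float = 9.0
    lights_on_hour: float = 21.0
    noise_temperature_c: float = 0.1
    noise_humidity_pct: float = 0.5
    noise_pressure_kpa: float = 0.05
    noise_lux: float = 0.0
    spike_rate_per_day: float = 0.0
    spike_lux: float = 300.0
    changepoint_day: int | None = None
    temperature_step_c: float = -1.0
    humidity_step_pct: float = 3.0

    def __post_init__(self):
        if not (0 <= self.lights_off_hour < 24 and 0 <= self.lights_on_hour < 24):
            raise DomainError("light-cycle clock hours must lie in [0, 24)")
        for name in ("noise_temperature_c", "noise_humidity_pct", "noise_pressure_kpa", "noise_lux"):
            if getattr(self, name) < 0:
                raise DomainError(f"{name} must be >= 0")
        if self.spike_rate_per_day < 0:
            raise DomainError("spike_rate_per_day must be >= 0")


def simulate_env(
    days: int,
    params: EnvParams = EnvParams(),
    rng: np.random.Generator | int = 0,
    *,
    start: datetime = datetime(2016, 7, 1),
) -> pd.DataFrame:
    """Simulate *days* of 10-min environmental samples (144/day), seeded.

    Lux is a square wave between ``lux_off`` (dark phase) and ``lux_on``
    driven by the configured clock times, with optional single-sample
    technician spikes during the dark phase; temperature and humidity take a
    step at ``changepoint_day`` when configured; every channel carries
    Gaussian sensor noise.
    """
    if days < 1:
        raise DomainError(f"days must be >= 1, got {days}")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    n = days * SAMPLES_PER_DAY
    times = pd.date_range(start, periods=n, freq=f"{SAMPLE_INTERVAL_MIN}min")
    hours = times.hour + times.minute / 60.0

    off, on = params.lights_off_hour, params.lights_on_hour
    if off < on:  # dark phase within one calendar day
        dark = (hours >= off) & (hours < on)
    else:
        dark = (hours >= off) | (hours < on)
    lux = np.where(dark, params.lux_off, params.lux_on).astype(float)

    if params.spike_rate_per_day > 0:
        n_spikes = rng.poisson(params.spike_rate_per_day * days)
        dark_idx = np.flatnonzero(dark)
        if dark_idx.size and n_spikes:
            hit = rng.choice(dark_idx, size=min(n_spikes, dark_idx.size), replace=False)
            lux[hit] += params.spike_lux

    temperature = np.full(n, params.temperature_c)
    humidity = np.full(n, params.humidity_pct)
    if params.changepoint_day is not None:
        k = int(params.changepoint_day) * SAMPLES_PER_DAY
        temperature[k:] += params.temperature_step_c
        humidity[k:] += params.humidity_step_pct
    pressure = np.full(n, params.pressure_kpa)

    temperature = temperature + rng.normal(0, params.noise_temperature_c, n)
    humidity = np.clip(humidity + rng.normal(0, params.noise_humidity_pct, n), 0.0, 100.0)
    pressure = pressure + rng.normal(0, params.noise_pressure_kpa, n)
    lux = np.maximum(lux + rng.normal(0, params.noise_lux, n), 0.0)

    return pd.DataFrame(
        {
            "time": times,
            "temperature_c": temperature,
            "humidity_pct": humidity,
            "pressure_kpa": pressure,
            "lux": lux,
        }
    )


def write_env_csv(series: pd.DataFrame, destination: Union[str, Path, IO[str]]) -> None:
    out = series.copy()
    out.insert(0, "time_iso", pd.to_datetime(out.pop("time")).map(lambda t: t.isoformat()))
    out.to_csv(destination, index=False)


def read_env_csv(source: Union[str, Path, IO[str]]) -> pd.DataFrame:
    df = pd.read_csv(source)
    df["time"] = pd.to_datetime(df.pop("time_iso"))
    return df[ENV_COLUMNS]


_VARIABLES = ["temperature_c", "humidity_pct", "pressure_kpa", "lux"]


def compare_devices(
    series_a: pd.DataFrame,
    series_b: pd.DataFrame,
    tolerance: pd.Timedelta = pd.Timedelta(minutes=5),
) -> pd.DataFrame:
    """Paired a-b differences per variable over timestamp-matched samples.

    Samples are matched by nearest timestamp within *tolerance* (half the
    nominal 10-min cadence by default). Returns a DataFrame indexed by
    variable with columns ``mean_diff``, ``sd_diff``, ``n``. Antisymmetric:
    swapping the inputs negates the means and leaves the SDs unchanged.
    """
    a = series_a.sort_values("time").reset_index(drop=True)
    b = series_b.sort_values("time").reset_index(drop=True)
    merged = pd.merge_asof(
        a, b, on="time", direction="nearest", tolerance=tolerance, suffixes=("_a", "_b")
    ).dropna()
    if len(merged) < 2:
        raise AlignmentError(
            f"series share only {len(merged)} timestamps within {tolerance}; need >= 2"
        )
    rows = {}
    for var in _VARIABLES:
        d = merged[f"{var}_a"] - merged[f"{var}_b"]
        rows[var] = {"mean_diff": d.mean(), "sd_diff": d.std(ddof=1), "n": len(d)}
    return pd.DataFrame.from_dict(rows, orient="index")[["mean_diff", "sd_diff", "n"]]


def detect_light_transitions(
    series: pd.DataFrame,
    lux_threshold: float | None = None,
    debounce: int = 2,
) -> list[tuple[pd.Timestamp, str]]:
    """Lights-on/off events from the lux trace.

    A transition is declared at the first sample of a run of at least
    *debounce* consecutive samples on the other side of the threshold;
    shorter excursions (single-sample technician spikes) are ignored, so the
    returned list alternates strictly between 'on' and 'off'. The default
    threshold is the midpoint of the series' 5th and 95th lux percentiles
    (the sensor is uncalibrated, so only relative level matters); a constant
    series yields an empty list.
    """
    if debounce < 1:
        raise DomainError("debounce must be >= 1")
    lux = series["lux"].to_numpy(dtype=float)
    times = pd.to_datetime(series["time"]).reset_index(drop=True)
    if lux.size == 0:
        return []
    if lux_threshold is None:
        lo, hi = np.percentile(lux, [5, 95])
        if hi - lo <= 0:
            return []
        lux_threshold = 0.5 * (lo + hi)
    above = lux > lux_threshold
    transitions: list[tuple[pd.Timestamp, str]] = []
    state = bool(above[0])
    i = 1
    n = above.size
    while i < n:
        if above[i] != state:
            run_end = i
            while run_end < n and above[run_end] == above[i]:
                run_end += 1
            if run_end - i >= debounce:
                state = bool(above[i])
                transitions.append((times[i], "on" if state else "off"))
            i = run_end
        else:
            i += 1
    return transitions


def estimate_step(
    series: pd.DataFrame,
    column: str,
    at: pd.Timestamp | datetime | None = None,
    min_segment: int = 6,
) -> tuple[pd.Timestamp, float]:
    """Size and location of a single mean shift in one variable.

    With *at* given, the step is simply mean(values at or after *at*) minus
    mean(values before). Otherwise the changepoint is located by minimising
    the two-segment residual sum of squares over all splits that leave at
    least *min_segment* samples on each side (the classic least-squares
    single-changepoint estimator). Returns (time of first post-step sample,
    step size).
    """
    x = series[column].to_numpy(dtype=float)
    times = pd.to_datetime(series["time"]).reset_index(drop=True)
    n = x.size
    if at is not None:
        mask = times >= pd.Timestamp(at)
        if mask.all() or not mask.any():
            raise DomainError(f"changepoint {at} does not split the series")
        k = int(np.argmax(mask.to_numpy()))
    else:
        if n < 2 * min_segment:
            raise DomainError(f"need at least {2 * min_segment} samples to locate a step")
        csum = np.cumsum(x)
        csq = np.cumsum(x**2)
        ks = np.arange(min_segment, n - min_segment + 1)  # split before index k
        left_n = ks.astype(float)
        right_n = n - left_n
        left_sum = csum[ks - 1]
        right_sum = csum[-1] - left_sum
        sse = (csq[ks - 1] - left_sum**2 / left_n) + (
            (csq[-1] - csq[ks - 1]) - right_sum**2 / right_n
        )
        k = int(ks[np.argmin(sse)])
    step = float(x[k:].mean() - x[:k].mean())
    return times[k], step
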