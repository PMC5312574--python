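"""Matplotlib figures for session and environmental data.

Each function draws onto a provided Axes (or a fresh one) and returns it, so
figures compose; the CLI saves them to files.
"""

from __future__ import annotations

from typing import Sequence

import matplotlib

matplotlib.use("Agg")  # headless tool: never require a display

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .analysis import LickCluster, bin_activity, cumulative_record
from .events import SessionRecord

__all__ = [
    "plot_cumulative_record",
    "plot_ili_histogram",
    "plot_cluster_size_histogram",
    "plot_activity",
    "plot_env_series",
]


def _ax(ax):
    if ax is None:
        _, ax = plt.subplots()
    return ax


def plot_cumulative_record(record: SessionRecord, ax=None):
    """Classic cumulative record: running lick and reward counts vs time."""
    ax = _ax(ax)
    series = cumulative_record(record)
    styles = {"active": "-", "inactive": "--", "reward": ":"}
    for name, df in series.items():
        ax.step(df["time_s"] / 60.0, df["count"], styles[name], where="post", label=name)
    ax.set_xlabel("time (min)")
    ax.set_ylabel("cumulative count")
    ax.legend(frameon=False)
    return ax


def plot_ili_histogram(clusters: Sequence[LickCluster], ax=None, bins=40):
    """Distribution of within-cluster inter-lick intervals."""
    ax = _ax(ax)
    if clusters:
        ilis = np.concatenate([c.ilis for c in clusters])
        ax.hist(ilis, bins=bins, range=(0, 0.5), color="tab:blue")
    ax.set_xlabel("inter-lick interval (s)")
    ax.set_ylabel("count")
    return ax


def plot_cluster_size_histogram(clusters: Sequence[LickCluster], ax=None, bins=30):
    ax = _ax(ax)
    if clusters:
        ax.hist([c.size for c in clusters], bins=bins, color="tab:orange")
    ax.set_xlabel("cluster size (licks)")
    ax.set_ylabel("count")
    return ax


def plot_activity(motion_times, session_s: float, bin_s: float = 60.0, ax=None):
    """Motion counts in 1-min bins across the session."""
    ax = _ax(ax)
    counts = bin_activity(motion_times, session_s, bin_s)
    ax.bar(np.arange(counts.size) * bin_s / 60.0, counts, width=bin_s / 60.0, align="edge")
    ax.set_xlabel("time (min)")
    ax.set_ylabel(f"motion events / {bin_s:g} s")
    return ax


def plot_env_series(series: pd.DataFrame, axes=None):
    """Four stacked panels: temperature, humidity, pressure, lux vs time."""
    if axes is None:
        _, axes = plt.subplots(4, 1, sharex=True, figsize=(8, 8))
    labels = {
        "temperature_c": "temperature (°C)",
        "humidity_pct": "humidity (%)",
        "pressure_kpa": "pressure (kPa)",
        "lux": "illuminance (lux)",
    }
    for ax, (col, label) in zip(axes, labels.items()):
        ax.plot(series["time"], series[col], lw=0.8)
        ax.set_ylabel(label)
    axes[-1].set_xlabel("time")
    return axes
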