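from __future__ import annotations

import numpy as np
import pytest

from licklab import Event, EventKind, ScheduleFamily, ScheduleSpec

TAG = "0A1B2C3D4E5F"


def random_lick_stream(rng, n_licks, active_frac=0.7, rate_hz=5.0, tag=TAG):
    """Raw input stream (leading scan + mixed-spout licks) for engine tests."""
    times = np.cumsum(rng.exponential(1.0 / rate_hz, size=n_licks))
    active = rng.random(n_licks) < active_frac
    events = [Event(0.0, EventKind.RFID_SCAN, tag)]
    events.extend(
        Event(float(t), EventKind.LICK_ACTIVE if a else EventKind.LICK_INACTIVE)
        for t, a in zip(times, active)
    )
    return events


def regular_licks(n, ili=0.15, start=0.0, tag=TAG):
    """Scan plus n active licks at a fixed inter-lick interval."""
    events = [Event(0.0, EventKind.RFID_SCAN, tag)]
    events.extend(Event(start + i * ili, EventKind.LICK_ACTIVE) for i in range(n))
    return events


@pytest.fixture
def rng():
    return np.random.default_rng(20160701)


@pytest.fixture
def fr10():
    return ScheduleSpec(ScheduleFamily.FR, ratio=10)


@pytest.fixture
def vr10():
    return ScheduleSpec(ScheduleFamily.VR, ratio=10)


@pytest.fixture
def pr_spec():
    return ScheduleSpec(ScheduleFamily.PR, ratio=10, pr_step=5)
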