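"""Reinforcement-schedule state machines and the session controller.

Three schedule families are implemented:

* **FR** (fixed ratio): a reward is delivered when a fixed number of counted
  licks on the active spout accumulates.
* **VR** (variable ratio): the requirement is redrawn after each reward,
  uniformly on {1, ..., 2*mean - 1}, so its expectation equals the nominal
  mean exactly. A fixed cycle of requirements can be supplied instead
  (``ScheduleSpec.vr_values``); a single-value cycle makes VR degenerate to FR.
* **PR** (progressive ratio): the requirement follows an arithmetic
  progression ``ratio + (k - 1) * pr_step`` for the k-th reward.

After every reward a timeout window ``[t_reward, t_reward + timeout_s)``
opens during which licks are logged but not counted toward the next
requirement (half-open: a lick landing exactly at the end of the timeout
counts). The cue light is lit at each reward for ``cue_s``; cue and timeout
windows run concurrently and independently.

The session controller :func:`run_session` turns a raw input stream (leading
RFID scan, then licks and motion) into a complete :class:`SessionRecord`:
the scan starts the session clock, active-spout licks drive the schedule,
inactive-spout licks are logged only, and the session ends after a fixed
duration (FR/VR) or a fixed idle window past the last active-spout lick (PR).

VR draw protocol (part of the engine contract, mirrored by any replay
implementation): one uniform draw when the state is initialised, then one
draw immediately after each reward.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta
from typing import Iterable

import numpy as np

from .errors import DomainError, OrderingError, ProtocolError, ValidationError
from .events import (
    Event,
    EventKind,
    ScheduleFamily,
    ScheduleSpec,
    SessionRecord,
    validate_tag,
)

__all__ = [
    "ScheduleState",
    "RfidScheduleMap",
    "initial_state",
    "fr_on_lick",
    "vr_on_lick",
    "pr_on_lick",
    "on_lick",
    "vr_draw_requirement",
    "pr_requirement",
    "resolve_schedule",
    "run_session",
    "DEFAULT_SESSION_START",
]

DEFAULT_SESSION_START = datetime(2016, 7, 1, 9, 0, 0)


def vr_draw_requirement(rng: np.random.Generator, mean: int) -> int:
    """Draw a VR requirement: uniform integer on {1, ..., 2*mean - 1}.

    The support is bounded, the minimum is 1, and the expectation equals
    *mean* exactly.
    """
    if mean < 1 or int(mean) != mean:
        raise DomainError(f"VR mean must be a positive integer, got {mean!r}")
    return int(rng.integers(1, 2 * int(mean)))


def pr_requirement(k: int, spec: ScheduleSpec) -> int:
    """Lick requirement for the k-th reward (k >= 1) under a PR schedule.

    Arithmetic progression: ``ratio + (k - 1) * pr_step``; strictly
    increasing in k.
    """
    if k < 1 or int(k) != k:
        raise DomainError(f"reward index must be >= 1, got {k!r}")
    return spec.ratio + (int(k) - 1) * spec.pr_step


@dataclass
class ScheduleState:
    """Mutable per-session schedule state.

    ``licks_toward_requirement`` stays strictly below
    ``current_requirement`` between rewards; ``timeout_until``, when set, is
    the end of the half-open post-reward timeout window.
    """

    current_requirement: int
    licks_toward_requirement: int = 0
    rewards_delivered: int = 0
    timeout_until: float | None = None
    cue_off_at: float | None = None
    last_active_lick_at: float | None = None
    rng: np.random.Generator | None = None
    vr_index: int = 0


def _next_vr_requirement(state: ScheduleState, spec: ScheduleSpec) -> int:
    if spec.vr_values is not None:
        req = spec.vr_values[state.vr_index % len(spec.vr_values)]
        state.vr_index += 1
        return req
    if state.rng is None:
        raise DomainError("VR schedule needs a seeded rng (or explicit vr_values)")
    return vr_draw_requirement(state.rng, spec.ratio)


def initial_state(spec: ScheduleSpec, rng: np.random.Generator | None = None) -> ScheduleState:
    """Fresh state for a session under *spec*; VR consumes one draw here."""
    state = ScheduleState(current_requirement=spec.ratio, rng=rng)
    if spec.family is ScheduleFamily.VR:
        state.current_requirement = _next_vr_requirement(state, spec)
    elif spec.family is ScheduleFamily.PR:
        state.current_requirement = pr_requirement(1, spec)
    return state


def on_lick(state: ScheduleState, t: float, spec: ScheduleSpec) -> tuple[ScheduleState, bool]:
    """Feed one active-spout lick at time *t*; returns (state, reward_issued).

    The state is updated in place (and also returned for convenience). Licks
    inside the post-reward timeout are logged by the caller but leave the
    requirement counter untouched.
    """
    if state.last_active_lick_at is not None and t < state.last_active_lick_at:
        raise OrderingError(
            f"lick at t={t} precedes previous lick at t={state.last_active_lick_at}"
        )
    state.last_active_lick_at = t
    if state.timeout_until is not None and t < state.timeout_until:
        return state, False  # recorded but no programmed consequence
    state.licks_toward_requirement += 1
    if state.licks_toward_requirement < state.current_requirement:
        return state, False
    # requirement met: reward, reset counter, open timeout + cue windows
    state.licks_toward_requirement = 0
    state.rewards_delivered += 1
    state.timeout_until = t + spec.timeout_s if spec.timeout_s > 0 else None
    state.cue_off_at = t + spec.cue_s
    if spec.family is ScheduleFamily.VR:
        state.current_requirement = _next_vr_requirement(state, spec)
    elif spec.family is ScheduleFamily.PR:
        state.current_requirement = pr_requirement(state.rewards_delivered + 1, spec)
    return state, True


def _family_on_lick(family: ScheduleFamily):
    def handler(state: ScheduleState, t: float, spec: ScheduleSpec):
        if spec.family is not family:
            raise DomainError(f"expected a {family.value} spec, got {spec.family.value}")
        return on_lick(state, t, spec)

    handler.__name__ = f"{family.value.lower()}_on_lick"
    handler.__doc__ = f"Active-spout lick under a {family.value} schedule; see :func:`on_lick`."
    return handler


fr_on_lick = _family_on_lick(ScheduleFamily.FR)
vr_on_lick = _family_on_lick(ScheduleFamily.VR)
pr_on_lick = _family_on_lick(ScheduleFamily.PR)


@dataclass(frozen=True)
class RfidScheduleMap:
    """Mapping from RFID tags to schedules, with a fall-back default.

    Scanning a mapped tag at session start selects that schedule; any other
    valid tag gets the default (VR with mean 10, matching the deployed
    device's behaviour). Multiple tags may map to the same schedule.
    """

    entries: dict[str, ScheduleSpec] = field(default_factory=dict)
    default: ScheduleSpec = field(default_factory=lambda: ScheduleSpec(ScheduleFamily.VR, ratio=10))

    def __post_init__(self):
        normalized = {}
        for tag, spec in self.entries.items():
            if not validate_tag(tag):
                raise ValidationError(f"RFID map key {tag!r} is not 12 hex characters")
            normalized[tag.upper()] = spec
        object.__setattr__(self, "entries", normalized)


def resolve_schedule(tag: str, schedule_map: RfidScheduleMap) -> ScheduleSpec:
    """Schedule for *tag*: the mapped spec if present, else the map default."""
    if not validate_tag(tag):
        raise ValidationError(f"invalid RFID tag {tag!r}")
    return schedule_map.entries.get(tag.upper(), schedule_map.default)


def run_session(
    input_events: Iterable[Event],
    spec: ScheduleSpec,
    *,
    rng: np.random.Generator | int | None = None,
    start_time: datetime = DEFAULT_SESSION_START,
    seed: int | None = None,
) -> SessionRecord:
    """Run the session controller over a raw input stream.

    Parameters
    ----------
    input_events
        Time-ordered stream whose first event is the ``rfid_scan`` that
        triggers the session; subsequent events are licks, motion, or
        further scans. Times may use any origin — they are rebased so the
        scan is t = 0.
    spec
        Governing schedule.
    rng
        Generator (or seed) for VR requirement draws; required for VR unless
        ``spec.vr_values`` is set.
    start_time
        Absolute wall-clock time of the scan, stored in the record sidecar.
    seed
        Recorded in the output for provenance; also used to build the rng
        when ``rng`` is None.

    Returns
    -------
    SessionRecord
        Complete, validated log: ``session_start`` and the scan at t = 0,
        all retained input events, ``reward``/``cue_on``/``cue_off`` events,
        and a final ``session_end``. FR/VR sessions span exactly
        ``session_s`` (input at or beyond the end is discarded); PR sessions
        end ``pr_idle_stop_s`` after the last active-spout lick, evaluated
        over the whole stream.
    """
    stream = list(input_events)
    if not stream:
        raise ProtocolError("empty input stream; a session starts with an rfid_scan")
    if stream[0].kind is not EventKind.RFID_SCAN:
        raise ProtocolError(
            f"first input event must be rfid_scan, got {stream[0].kind.value}"
        )
    t0 = stream[0].time
    subject_tag = stream[0].tag
    times = np.fromiter((e.time for e in stream), dtype=float, count=len(stream))
    if (np.diff(times) < 0).any():
        i = int(np.argmax(np.diff(times) < 0)) + 1
        raise OrderingError(f"input event {i}: time decreases")
    rel = times - t0

    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    elif rng is None and seed is not None:
        rng = np.random.default_rng(seed)
    state = initial_state(spec, rng)

    if spec.family is ScheduleFamily.PR:
        active = [rel[i] for i, e in enumerate(stream) if e.kind is EventKind.LICK_ACTIVE]
        last_active = active[-1] if active else 0.0
        end_t = last_active + spec.pr_idle_stop_s
        keep = rel <= end_t
    else:
        end_t = spec.session_s
        keep = rel < end_t  # session is the half-open window [0, session_s)

    out: list[Event] = [
        Event(0.0, EventKind.SESSION_START),
        Event(0.0, EventKind.RFID_SCAN, subject_tag),
    ]
    pending_cue_off: float | None = None
    for i in range(1, len(stream)):
        if not keep[i]:
            continue
        e, t = stream[i], float(rel[i])
        if pending_cue_off is not None and pending_cue_off <= t:
            out.append(Event(pending_cue_off, EventKind.CUE_OFF))
            pending_cue_off = None
        if e.kind is EventKind.LICK_ACTIVE:
            out.append(Event(t, EventKind.LICK_ACTIVE))
            _, rewarded = on_lick(state, t, spec)
            if rewarded:
                if pending_cue_off is not None:  # overlapping cue: close it early
                    out.append(Event(t, EventKind.CUE_OFF))
                out.append(Event(t, EventKind.REWARD))
                if spec.cue_s > 0:
                    out.append(Event(t, EventKind.CUE_ON))
                    pending_cue_off = t + spec.cue_s
        elif e.kind is EventKind.RFID_SCAN:
            out.append(Event(t, EventKind.RFID_SCAN, e.tag))
        else:
            out.append(Event(t, e.kind))
    if pending_cue_off is not None:
        out.append(Event(min(pending_cue_off, end_t), EventKind.CUE_OFF))
    out.append(Event(end_t, EventKind.SESSION_END))

    return SessionRecord.build(
        subject_tag=subject_tag,
        schedule=spec,
        start_time=start_time,
        end_time=start_time + timedelta(seconds=end_t),
        events=out,
        seed=seed,
    )
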