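"""Core domain types for operant-licking sessions and the event-log CSV format.

A session is a time-ordered stream of :class:`Event` objects — licks on the
active or inactive spout, motion-sensor triggers, reward deliveries, cue-light
transitions, RFID scans, and the session boundaries — wrapped in a
:class:`SessionRecord` together with the subject's RFID tag and the
:class:`ScheduleSpec` that governed the session.

The on-disk format is a plain CSV with a ``#``-prefixed metadata sidecar::

    # licklab event log v1
    # subject_tag: 0A1B2C3D4E5F
    # family: FR
    # ratio: 10
    ...
    time_s,kind,tag
    0.000,session_start,
    0.000,rfid_scan,0A1B2C3D4E5F
    ...

Times are seconds since session start, written as shortest decimal text that
round-trips the underlying float exactly (padded to at least three fractional
digits — rat licks are ~0.15 s apart, so millisecond resolution matters).
Equal timestamps are legal (a touch and a motion trigger can coincide); their
relative order is preserved exactly, both in memory and through the CSV.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from datetime import datetime
from enum import Enum
from pathlib import Path
from typing import IO, Iterable, Union

import numpy as np

from .errors import OrderingError, ParseError, ValidationError

__all__ = [
    "EventKind",
    "ScheduleFamily",
    "Event",
    "ScheduleSpec",
    "SessionRecord",
    "validate_tag",
    "read_event_log",
    "write_event_log",
    "read_event_stream",
    "write_event_stream",
]

_TAG_RE = re.compile(r"^[0-9a-fA-F]{12}$")


def validate_tag(text: str) -> bool:
    """Return True iff *text* is a 12-character hexadecimal RFID tag.

    Glass RFID transponders encode a twelve-character hexadecimal subject
    identifier; this is a total function (never raises).
    """
    return isinstance(text, str) and bool(_TAG_RE.match(text))


class EventKind(str, Enum):
    LICK_ACTIVE = "lick_active"
    LICK_INACTIVE = "lick_inactive"
    MOTION = "motion"
    REWARD = "reward"
    CUE_ON = "cue_on"
    CUE_OFF = "cue_off"
    RFID_SCAN = "rfid_scan"
    SESSION_START = "session_start"
    SESSION_END = "session_end"


class ScheduleFamily(str, Enum):
    FR = "FR"  # fixed ratio: reward every `ratio` counted licks
    VR = "VR"  # variable ratio: random requirement with mean `ratio`
    PR = "PR"  # progressive ratio: requirement grows by `pr_step` per reward


@dataclass(frozen=True, slots=True)
class Event:
    """One timestamped occurrence within a session.

    Parameters
    ----------
    time : float
        Seconds since session start (non-negative).
    kind : EventKind or str
        Event type.
    tag : str, optional
        12-character hexadecimal RFID tag; present iff ``kind`` is
        ``rfid_scan``.
    """

    time: float
    kind: EventKind
    tag: str | None = None

    def __post_init__(self):
        if not isinstance(self.kind, EventKind):
            object.__setattr__(self, "kind", EventKind(self.kind))
        t = float(self.time)
        if not np.isfinite(t) or t < 0.0:
            raise ValidationError(f"event time must be finite and >= 0, got {self.time!r}")
        object.__setattr__(self, "time", t)
        if self.kind is EventKind.RFID_SCAN:
            if self.tag is None or not validate_tag(self.tag):
                raise ValidationError(
                    f"rfid_scan requires a 12-hex-character tag, got {self.tag!r}"
                )
        elif self.tag is not None:
            raise ValidationError(f"tag is only allowed on rfid_scan events, got kind={self.kind.value}")


@dataclass(frozen=True, slots=True)
class ScheduleSpec:
    """Parameters of a reinforcement schedule.

    ``ratio`` is the FR requirement, the VR mean, or the PR base requirement.
    ``pr_step`` is the PR arithmetic increment (requirement_k = ratio +
    (k-1)*pr_step). After each reward a ``timeout_s`` window starts during
    which licks are logged but not counted, and the cue light is lit for
    ``cue_s``. FR/VR sessions run for a fixed ``session_s``; PR sessions end
    ``pr_idle_stop_s`` after the last active-spout lick.

    ``vr_values``, when given, replaces the random VR draw with a fixed cycle
    of requirements (useful for deterministic replays; a single value makes VR
    degenerate to FR).
    """

    family: ScheduleFamily
    ratio: int = 10
    pr_step: int = 5
    timeout_s: float = 20.0
    cue_s: float = 5.0
    session_s: float = 3600.0
    pr_idle_stop_s: float = 600.0
    vr_values: tuple[int, ...] | None = None

    def __post_init__(self):
        if not isinstance(self.family, ScheduleFamily):
            object.__setattr__(self, "family", ScheduleFamily(self.family))
        if int(self.ratio) != self.ratio or self.ratio < 1:
            raise ValidationError(f"ratio must be a positive integer, got {self.ratio!r}")
        object.__setattr__(self, "ratio", int(self.ratio))
        if int(self.pr_step) != self.pr_step or self.pr_step < 1:
            raise ValidationError(f"pr_step must be a positive integer, got {self.pr_step!r}")
        object.__setattr__(self, "pr_step", int(self.pr_step))
        for name in ("timeout_s", "cue_s"):
            v = float(getattr(self, name))
            if not np.isfinite(v) or v < 0:
                raise ValidationError(f"{name} must be >= 0, got {v!r}")
            object.__setattr__(self, name, v)
        for name in ("session_s", "pr_idle_stop_s"):
            v = float(getattr(self, name))
            if not np.isfinite(v) or v <= 0:
                raise ValidationError(f"{name} must be > 0, got {v!r}")
            object.__setattr__(self, name, v)
        if self.vr_values is not None:
            vals = tuple(int(v) for v in self.vr_values)
            if not vals or any(v < 1 for v in vals):
                raise ValidationError("vr_values must be a non-empty sequence of positive integers")
            object.__setattr__(self, "vr_values", vals)


@dataclass(frozen=True)
class SessionRecord:
    """One animal's session: identity, schedule, boundaries, and event log.

    Invariants (enforced by :meth:`validate`): events are sorted by time with
    ties kept in input order; the first event is ``session_start`` and the
    last is ``session_end``; ``rewards`` equals the number of reward events;
    ``end_time >= start_time``.
    """

    subject_tag: str
    schedule: ScheduleSpec
    start_time: datetime
    end_time: datetime
    events: tuple[Event, ...]
    rewards: int
    seed: int | None = None

    def __post_init__(self):
        object.__setattr__(self, "events", tuple(self.events))

    @classmethod
    def build(
        cls,
        subject_tag: str,
        schedule: ScheduleSpec,
        start_time: datetime,
        end_time: datetime,
        events: Iterable[Event],
        seed: int | None = None,
    ) -> "SessionRecord":
        """Construct a record, deriving the reward count from the events."""
        evs = tuple(events)
        rewards = sum(1 for e in evs if e.kind is EventKind.REWARD)
        rec = cls(subject_tag, schedule, start_time, end_time, evs, rewards, seed)
        rec.validate()
        return rec

    def validate(self) -> None:
        """Raise :class:`ValidationError` naming the first offending event index."""
        if not validate_tag(self.subject_tag):
            raise ValidationError(f"subject_tag {self.subject_tag!r} is not 12 hex characters")
        if self.end_time < self.start_time:
            raise ValidationError("end_time precedes start_time")
        if len(self.events) < 2:
            raise ValidationError("a session needs at least session_start and session_end events")
        if self.events[0].kind is not EventKind.SESSION_START:
            raise ValidationError("event 0: first event must be session_start")
        last = len(self.events) - 1
        if self.events[last].kind is not EventKind.SESSION_END:
            raise ValidationError(f"event {last}: last event must be session_end")
        times = np.fromiter((e.time for e in self.events), dtype=float, count=len(self.events))
        bad = np.diff(times) < 0
        if bad.any():
            i = int(np.argmax(bad)) + 1
            raise OrderingError(f"event {i}: time {times[i]} precedes previous event at {times[i - 1]}")
        n_rewards = sum(1 for e in self.events if e.kind is EventKind.REWARD)
        if n_rewards != self.rewards:
            raise ValidationError(
                f"rewards field is {self.rewards} but log contains {n_rewards} reward events"
            )

    @property
    def duration_s(self) -> float:
        return self.events[-1].time - self.events[0].time

    def events_of(self, kind: EventKind) -> list[Event]:
        return [e for e in self.events if e.kind is kind]

    def lick_times(self, spout: str = "active") -> np.ndarray:
        """Times of licks on one spout, as a float array."""
        kind = EventKind.LICK_ACTIVE if spout == "active" else EventKind.LICK_INACTIVE
        return np.fromiter((e.time for e in self.events if e.kind is kind), dtype=float)


# ---------------------------------------------------------------------------
# CSV serialization


def _format_time(t: float) -> str:
    # shortest representation that parses back to the same float, padded to
    # >= 3 fractional digits (appending zeros never changes the value)
    s = np.format_float_positional(t, unique=True, trim="0")
    if "." not in s:
        return s + ".000"
    frac = len(s) - s.index(".") - 1
    return s + "0" * max(0, 3 - frac)


_SIDE_CAR_MAGIC = "licklab event log v1"
_HEADER = "time_s,kind,tag"


def write_event_log(record: SessionRecord, destination: Union[str, Path, IO[str]]) -> None:
    """Write *record* to CSV; round-trips losslessly through :func:`read_event_log`."""
    record.validate()
    sched = record.schedule
    lines = [
        f"# {_SIDE_CAR_MAGIC}",
        f"# subject_tag: {record.subject_tag}",
        f"# family: {sched.family.value}",
        f"# ratio: {sched.ratio}",
        f"# pr_step: {sched.pr_step}",
        f"# timeout_s: {sched.timeout_s!r}",
        f"# cue_s: {sched.cue_s!r}",
        f"# session_s: {sched.session_s!r}",
        f"# pr_idle_stop_s: {sched.pr_idle_stop_s!r}",
    ]
    if sched.vr_values is not None:
        lines.append("# vr_values: " + ",".join(str(v) for v in sched.vr_values))
    if record.seed is not None:
        lines.append(f"# seed: {record.seed}")
    lines.append(f"# start_time: {record.start_time.isoformat()}")
    lines.append(f"# end_time: {record.end_time.isoformat()}")
    lines.append(_HEADER)
    for e in record.events:
        lines.append(f"{_format_time(e.time)},{e.kind.value},{e.tag or ''}")
    text = "\n".join(lines) + "\n"
    if hasattr(destination, "write"):
        destination.write(text)
    else:
        Path(destination).write_text(text, encoding="utf-8")


def _parse_csv_body(text: str) -> tuple[list[Event], dict[str, str]]:
    """Shared CSV parser: returns (events, sidecar metadata)."""
    meta: dict[str, str] = {}
    events: list[Event] = []
    saw_header = False
    for ln, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line[1:].strip()
            if ":" in body:
                key, _, val = body.partition(":")
                meta[key.strip()] = val.strip()
            continue
        if not saw_header:
            if line != _HEADER:
                raise ParseError(f"expected header {_HEADER!r}, got {line!r}", line=ln)
            saw_header = True
            continue
        parts = line.split(",")
        if len(parts) != 3:
            raise ParseError(f"expected 3 fields, got {len(parts)}", line=ln)
        t_text, kind_text, tag_text = parts
        try:
            t = float(t_text)
        except ValueError:
            raise ParseError(f"bad time {t_text!r}", line=ln) from None
        try:
            kind = EventKind(kind_text)
        except ValueError:
            raise ParseError(f"unknown event kind {kind_text!r}", line=ln) from None
        try:
            events.append(Event(t, kind, tag_text or None))
        except ValidationError as exc:
            raise ParseError(str(exc), line=ln) from None
    if not saw_header:
        raise ParseError(f"missing header {_HEADER!r}")

    return events, meta


def write_event_stream(events: Iterable[Event], destination: Union[str, Path, IO[str]]) -> None:
    """Write a raw (boundary-free) input stream — e.g. simulator output — as CSV."""
    lines = ["# licklab event stream v1", _HEADER]
    for e in events:
        lines.append(f"{_format_time(e.time)},{e.kind.value},{e.tag or ''}")
    text = "\n".join(lines) + "\n"
    if hasattr(destination, "write"):
        destination.write(text)
    else:
        Path(destination).write_text(text, encoding="utf-8")


def read_event_stream(source: Union[str, Path, IO[str]]) -> list[Event]:
    """Read a raw input stream CSV (no session boundaries or sidecar required)."""
    if hasattr(source, "read"):
        text = source.read()
    else:
        text = Path(source).read_text(encoding="utf-8")
    events, _ = _parse_csv_body(text)
    return events


def read_event_log(source: Union[str, Path, IO[str]]) -> SessionRecord:
    """Parse a CSV event log back into a validated :class:`SessionRecord`.

    Raises :class:`ParseError` with a line number for malformed rows and
    :class:`ValidationError`/:class:`OrderingError` for invariant violations.
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        text = Path(source).read_text(encoding="utf-8")
    events, meta = _parse_csv_body(text)

    required = ("subject_tag", "family", "ratio", "start_time", "end_time")
    for key in required:
        if key not in meta:
            raise ParseError(f"missing sidecar field {key!r}")
    kwargs: dict = {"family": ScheduleFamily(meta["family"]), "ratio": int(meta["ratio"])}
    for name in ("timeout_s", "cue_s", "session_s", "pr_idle_stop_s"):
        if name in meta:
            kwargs[name] = float(meta[name])
    if "pr_step" in meta:
        kwargs["pr_step"] = int(meta["pr_step"])
    if "vr_values" in meta:
        kwargs["vr_values"] = tuple(int(v) for v in meta["vr_values"].split(","))
    try:
        schedule = ScheduleSpec(**kwargs)
    except ValidationError as exc:
        raise ParseError(f"bad schedule sidecar: {exc}") from None
    seed = int(meta["seed"]) if "seed" in meta else None
    record = SessionRecord(
        subject_tag=meta["subject_tag"],
        schedule=schedule,
        start_time=datetime.fromisoformat(meta["start_time"]),
        end_time=datetime.fromisoformat(meta["end_time"]),
        events=tuple(events),
        rewards=sum(1 for e in events if e.kind is EventKind.REWARD),
        seed=seed,
    )
    record.validate()
    return record
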