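"""Named presets and YAML configuration files.

Schedules can be referenced by name (``fr10``, ``vr10``, ``pr``) or loaded
from a YAML file whose keys mirror :class:`~licklab.events.ScheduleSpec`
fields. RFID maps and cohort specifications are also YAML:

RFID map::

    default: vr10
    tags:
      0A1B2C3D4E5F: fr10
      F00D0A1B2C3D: {family: PR, ratio: 10, pr_step: 5}

Cohort::

    rats:
      - {preset: sucrose, seed: 11}
      - {preset: water, seed: 12, active_preference: 0.8}
"""

from __future__ import annotations

from pathlib import Path
from typing import Union

import yaml

from .errors import ValidationError
from .events import ScheduleFamily, ScheduleSpec
from .schedules import RfidScheduleMap
from .virtual_rat import RatParams, sucrose_like, water_like

__all__ = [
    "SCHEDULE_PRESETS",
    "RAT_PRESETS",
    "get_schedule",
    "load_schedule_file",
    "load_rfid_map",
    "load_cohort",
]

SCHEDULE_PRESETS: dict[str, ScheduleSpec] = {
    "fr10": ScheduleSpec(ScheduleFamily.FR, ratio=10),
    "vr10": ScheduleSpec(ScheduleFamily.VR, ratio=10),
    "pr": ScheduleSpec(ScheduleFamily.PR, ratio=10, pr_step=5),
}

RAT_PRESETS = {"sucrose": sucrose_like, "water": water_like}


def _spec_from_mapping(data: dict) -> ScheduleSpec:
    allowed = {
        "family",
        "ratio",
        "pr_step",
        "timeout_s",
        "cue_s",
        "session_s",
        "pr_idle_stop_s",
        "vr_values",
    }
    unknown = set(data) - allowed
    if unknown:
        raise ValidationError(f"unknown schedule fields: {sorted(unknown)}")
    if "family" not in data:
        raise ValidationError("schedule config needs a 'family' field")
    kwargs = dict(data)
    if "vr_values" in kwargs and kwargs["vr_values"] is not None:
        kwargs["vr_values"] = tuple(kwargs["vr_values"])
    return ScheduleSpec(**kwargs)


def get_schedule(name_or_path: Union[str, Path]) -> ScheduleSpec:
    """Resolve a preset name (``fr10``/``vr10``/``pr``) or a YAML file path."""
    key = str(name_or_path).lower()
    if key in SCHEDULE_PRESETS:
        return SCHEDULE_PRESETS[key]
    path = Path(name_or_path)
    if path.exists():
        return load_schedule_file(path)
    raise ValidationError(
        f"unknown schedule {name_or_path!r}: not a preset ({sorted(SCHEDULE_PRESETS)}) or a file"
    )


def load_schedule_file(path: Union[str, Path]) -> ScheduleSpec:
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict):
        raise ValidationError(f"{path}: schedule config must be a mapping")
    return _spec_from_mapping(data)


def _resolve_entry(value) -> ScheduleSpec:
    if isinstance(value, str):
        return get_schedule(value)
    if isinstance(value, dict):
        return _spec_from_mapping(value)
    raise ValidationError(f"cannot interpret schedule entry {value!r}")


def load_rfid_map(path: Union[str, Path]) -> RfidScheduleMap:
    data = yaml.safe_load(Path(path).read_text()) or {}
    default = _resolve_entry(data.get("default", "vr10"))
    entries = {tag: _resolve_entry(v) for tag, v in (data.get("tags") or {}).items()}
    return RfidScheduleMap(entries=entries, default=default)


def load_cohort(path: Union[str, Path]) -> list[tuple[RatParams, int]]:
    """Load a cohort spec: list of (RatParams, seed) pairs."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    rats = data.get("rats")
    if not isinstance(rats, list) or not rats:
        raise ValidationError(f"{path}: cohort config needs a non-empty 'rats' list")
    out = []
    for i, entry in enumerate(rats):
        if not isinstance(entry, dict) or "seed" not in entry:
            raise ValidationError(f"{path}: rat {i} needs at least a 'seed'")
        entry = dict(entry)
        seed = int(entry.pop("seed"))
        preset = entry.pop("preset", "sucrose")
        if preset not in RAT_PRESETS:
            raise ValidationError(f"{path}: unknown preset {preset!r} for rat {i}")
        out.append((RAT_PRESETS[preset](**entry), seed))
    return out
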