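"""JSON run configuration.

A config file holds one optional section per pipeline stage; every
field defaults to the module's defaults and unknown keys are rejected
so typos fail loudly::

    {
      "preprocess": {"mains_hz": 50, "mode": "NOTCH"},
      "beats": {"threshold_frac": 0.6},
      "anatomy": {"RA": [-0.5263, 2.201, -1.311]},
      "hemodynamics": {"window_s": 30, "window_start_s": 0},
      "synth": {"hr_bpm": 60, "seed": 0}
    }
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

from .anatomy import LengthModel
from .beats import DetectorSettings
from .errors import ConfigError
from .preprocess import FilterSettings
from .synth import SynthSettings

_SECTIONS = ("preprocess", "beats", "anatomy", "hemodynamics", "synth", "io", "verbosity")


@dataclass(frozen=True)
class RunConfig:
    preprocess: FilterSettings = FilterSettings()
    beats: DetectorSettings = DetectorSettings()
    anatomy: LengthModel = field(default_factory=LengthModel.default)
    window_s: float = 30.0
    window_start_s: float = 0.0
    synth: SynthSettings = SynthSettings()
    io: dict = field(default_factory=dict)
    verbosity: int = 0


def _build(cls, section: dict, name: str):
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(section) - valid
    if unknown:
        raise ConfigError(f"unknown keys in section '{name}': {sorted(unknown)}")
    try:
        return cls(**section)
    except TypeError as exc:
        raise ConfigError(f"invalid section '{name}': {exc}") from exc


def load_config(path: Optional[Union[str, Path]] = None) -> RunConfig:
    """Parse a JSON config file; ``None`` yields all defaults."""
    if path is None:
        return RunConfig()
    raw = json.loads(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a JSON object")
    unknown = set(raw) - set(_SECTIONS)
    if unknown:
        raise ConfigError(f"unknown config sections: {sorted(unknown)}")

    hemo = dict(raw.get("hemodynamics", {}))
    hemo_unknown = set(hemo) - {"window_s", "window_start_s"}
    if hemo_unknown:
        raise ConfigError(f"unknown keys in section 'hemodynamics': {sorted(hemo_unknown)}")
    if "ecg_keep_details" in raw.get("preprocess", {}):
        sect = dict(raw["preprocess"])
        sect["ecg_keep_details"] = frozenset(sect["ecg_keep_details"])
        raw = {**raw, "preprocess": sect}

    return RunConfig(
        preprocess=_build(FilterSettings, raw.get("preprocess", {}), "preprocess"),
        beats=_build(DetectorSettings, raw.get("beats", {}), "beats"),
        anatomy=LengthModel.from_json(raw.get("anatomy", {})),
        window_s=float(hemo.get("window_s", 30.0)),
        window_start_s=float(hemo.get("window_start_s", 0.0)),
        synth=_build(SynthSettings, raw.get("synth", {}), "synth"),
        io=dict(raw.get("io", {})),
        verbosity=int(raw.get("verbosity", 0)),
    )
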