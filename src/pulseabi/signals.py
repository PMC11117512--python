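"""Core signal containers, plain-text stream I/O, and the embedded validation table.

A recording session pairs one ECG channel (chest) with two PPG channels
(index fingertip and hallux) sampled simultaneously on one body side.
All timing is derived from sample indices: sample ``i`` of a channel
occurs at ``t0 + i / fs`` seconds (0-based).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Sequence, Union

import numpy as np

from .errors import EmptyInputError, ParseError, ConfigError, FixtureError

DEFAULT_FS = 200.0  # Hz — acquisition rate of the measurement device


class Channel(str, Enum):
    ECG = "ECG"
    PPG_HAND = "PPG_HAND"
    PPG_FOOT = "PPG_FOOT"


class Side(str, Enum):
    RIGHT = "RIGHT"
    LEFT = "LEFT"


@dataclass(frozen=True)
class SampledSignal:
    """One uniformly sampled channel.

    Parameters
    ----------
    values : array-like of float
        Raw samples in arbitrary voltage-like units; must be finite and
        non-empty.
    channel : Channel
        Physiological role of the channel.
    side : Side
        Body side the channel was recorded on.
    fs : float
        Sampling rate in Hz (default 200).
    t0 : float
        Start-time offset in seconds, used for manual alignment of
        independently clocked devices.
    """

    values: np.ndarray
    channel: Channel
    side: Side
    fs: float = DEFAULT_FS
    t0: float = 0.0

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1:
            raise ConfigError("signal values must be one-dimensional")
        if v.size < 1:
            raise EmptyInputError("signal must contain at least one sample")
        if not np.all(np.isfinite(v)):
            raise ConfigError("signal values must all be finite")
        if not self.fs > 0:
            raise ConfigError(f"sampling rate must be positive, got {self.fs}")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "channel", Channel(self.channel))
        object.__setattr__(self, "side", Side(self.side))

    def __len__(self) -> int:
        return self.values.size

    @property
    def duration_s(self) -> float:
        return (self.values.size - 1) / self.fs

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds: ``t0 + i / fs``."""
        return self.t0 + np.arange(self.values.size) / self.fs

    def with_values(self, values: np.ndarray) -> "SampledSignal":
        """Copy of this signal with replaced samples (metadata preserved)."""
        return SampledSignal(values, self.channel, self.side, self.fs, self.t0)


@dataclass(frozen=True)
class RecordingSession:
    """Clock-synchronised ECG + hand PPG + foot PPG for one body side."""

    ecg: SampledSignal
    ppg_hand: SampledSignal
    ppg_foot: SampledSignal
    height_m: float
    side: Side

    def __post_init__(self):
        object.__setattr__(self, "side", Side(self.side))
        roles = {
            "ecg": (self.ecg, Channel.ECG),
            "ppg_hand": (self.ppg_hand, Channel.PPG_HAND),
            "ppg_foot": (self.ppg_foot, Channel.PPG_FOOT),
        }
        for name, (sig, want) in roles.items():
            if sig.channel is not want:
                raise ConfigError(
                    f"{name} channel role is {sig.channel.value}, expected {want.value}"
                )
            if sig.side is not self.side:
                raise ConfigError(f"{name} recorded on {sig.side.value}, session is {self.side.value}")
            if sig.fs != self.ecg.fs:
                raise ConfigError("all channels must share one sampling rate")
        if not (0.5 < self.height_m < 3.0):
            raise ConfigError(f"implausible height {self.height_m} m")

    @property
    def fs(self) -> float:
        return self.ecg.fs

    @property
    def duration_s(self) -> float:
        return min(self.ecg.duration_s, self.ppg_hand.duration_s, self.ppg_foot.duration_s)


@dataclass(frozen=True)
class SubjectRecord:
    """One row of the 22-subject validation table.

    ``trad_censored`` marks incompressible-artery readings that the
    Doppler reference method could only report as ">1.30"; the numeric
    fields then hold 1.30.
    """

    subject_id: int
    sex: str  # "F" or "M"
    age: float
    weight_kg: float
    height_m: float
    abi_trad_right: float
    abi_trad_left: float
    abi_sys_right: float
    abi_sys_left: float
    trad_censored: bool = False

    def __post_init__(self):
        if self.sex not in ("F", "M"):
            raise FixtureError(f"sex must be 'F' or 'M', got {self.sex!r}")
        for v in (self.abi_trad_right, self.abi_trad_left, self.abi_sys_right, self.abi_sys_left):
            if not (0 < v < 2):
                raise FixtureError(f"ABI {v} outside (0, 2)")
        if not (1.4 <= self.height_m <= 2.0):
            raise FixtureError(f"height {self.height_m} outside [1.4, 2.0]")


def _parse_row(fields: Sequence[str], row_number: int) -> float:
    """Parse one data row; with >=2 columns the leading timestamp is dropped."""
    cell = fields[-1] if len(fields) > 1 else fields[0]
    try:
        return float(cell)
    except ValueError:
        raise ParseError(f"non-numeric sample {cell!r} at row {row_number}") from None


def _split(line: str) -> list[str]:
    if "," in line:
        return [f.strip() for f in line.split(",")]
    return line.split()


def read_signal_stream(
    path: Union[str, Path],
    fs: float = DEFAULT_FS,
    channel: Channel = Channel.ECG,
    side: Side = Side.RIGHT,
    t0: float = 0.0,
) -> SampledSignal:
    """Read one channel from a plain-text stream (one sample per row).

    Accepts comma- or whitespace-separated rows, an optional single
    header line, and an optional leading timestamp column (auto-detected
    and dropped: only the last column is kept when a row has several).
    """
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise EmptyInputError(f"no samples in {path}")

    start = 0
    # header detection: first line fails numeric parse on every column
    first = _split(lines[0])
    try:
        [float(c) for c in first]
    except ValueError:
        start = 1
    if start == len(lines):
        raise EmptyInputError(f"no samples after header in {path}")

    values = [_parse_row(_split(ln), i + 1) for i, ln in enumerate(lines[start:], start=start)]
    return SampledSignal(np.array(values), channel, side, fs, t0)


def write_signal_stream(signal: SampledSignal, path: Union[str, Path]) -> None:
    """Write one sample per row at full precision (round-trips exactly)."""
    path = Path(path)
    with path.open("w") as fh:
        for v in signal.values:
            fh.write(f"{float(v)!r}\n")


# Embedded 22-subject validation table; column order documented in data/table1.csv.
_TABLE1_RESOURCE = "table1.csv"


def load_table1() -> list[SubjectRecord]:
    """Load the embedded 22-subject validation table.

    Returns the 9 female subjects followed by the 13 male subjects.
    Subject 11's traditional-method readings (">1.30", incompressible
    arteries) are stored as 1.30 with ``trad_censored=True``.
    """
    text = resources.files("pulseabi").joinpath("data", _TABLE1_RESOURCE).read_text()
    rows = list(csv.DictReader(text.splitlines()))
    if len(rows) != 22:
        raise FixtureError(f"expected 22 subjects, found {len(rows)}")
    records = [
        SubjectRecord(
            subject_id=int(r["id"]),
            sex=r["sex"],
            age=float(r["age"]),
            weight_kg=float(r["weight_kg"]),
            height_m=float(r["height_m"]),
            abi_trad_right=float(r["trad_r"]),
            abi_trad_left=float(r["trad_l"]),
            abi_sys_right=float(r["sys_r"]),
            abi_sys_left=float(r["sys_l"]),
            trad_censored=r["censored"] == "1",
        )
        for r in rows
    ]
    return records
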