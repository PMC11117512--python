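"""Height-driven arterial path lengths.

Arterial path length cannot be measured directly in a screening
setting, so each of five segments is modelled as a quadratic in subject
height H (metres): length = a*H^2 + b*H + c. The five segments are

* RA / LA — heart (sternal end of the left clavicle) to right/left
  index fingertip,
* AR / AL — heart to right/left heel,
* PA — heel to the midpoint of the hallux (plantar arch).

The heart-to-hallux distance on each side is the sum AR+PA (right) or
AL+PA (left). The default coefficients were fitted by least squares on
surface measurements of 35 adults; the model is only trusted for adult
heights and raises outside [1.0, 2.5] m.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Sequence

import numpy as np

from .errors import HeightRangeError, RankError
from .signals import Side

HEIGHT_MIN_M = 1.0
HEIGHT_MAX_M = 2.5


class Segment(str, Enum):
    RA = "RA"  # heart -> right index finger
    LA = "LA"  # heart -> left index finger
    AR = "AR"  # heart -> right heel
    AL = "AL"  # heart -> left heel
    PA = "PA"  # heel -> hallux (plantar)


#: default quadratic coefficients (a, b, c), metres vs height in metres
DEFAULT_COEFFS: dict[Segment, tuple[float, float, float]] = {
    Segment.RA: (-0.5263, 2.201, -1.311),
    Segment.LA: (-0.5018, 2.083, -1.245),
    Segment.AR: (-0.3993, 1.967, -0.8949),
    Segment.AL: (-0.5543, 2.488, -1.336),
    Segment.PA: (-0.2921, 1.055, -0.736),
}


@dataclass(frozen=True)
class LengthModel:
    """Per-segment quadratic coefficients (a, b, c)."""

    coeffs: Mapping[Segment, tuple[float, float, float]]

    @classmethod
    def default(cls) -> "LengthModel":
        return cls(dict(DEFAULT_COEFFS))

    def to_json(self) -> dict:
        return {seg.value: list(abc) for seg, abc in self.coeffs.items()}

    @classmethod
    def from_json(cls, obj: Mapping[str, Sequence[float]]) -> "LengthModel":
        coeffs = dict(DEFAULT_COEFFS)
        for key, abc in obj.items():
            coeffs[Segment(key)] = tuple(float(v) for v in abc)
        return cls(coeffs)


@dataclass(frozen=True)
class CompositeLengths:
    """Side-resolved path lengths for one subject height."""

    ra_m: float  # heart -> right hand
    la_m: float  # heart -> left hand
    arf_m: float  # heart -> right hallux (AR + PA)
    alf_m: float  # heart -> left hallux (AL + PA)

    def hand_m(self, side: Side) -> float:
        return self.ra_m if Side(side) is Side.RIGHT else self.la_m

    def foot_m(self, side: Side) -> float:
        return self.arf_m if Side(side) is Side.RIGHT else self.alf_m


def _check_height(height_m: float) -> None:
    if not (HEIGHT_MIN_M <= height_m <= HEIGHT_MAX_M):
        raise HeightRangeError(
            f"height {height_m} m outside [{HEIGHT_MIN_M}, {HEIGHT_MAX_M}]: "
            "quadratic length model not valid under extrapolation"
        )


def segment_length(model: LengthModel, segment: Segment, height_m: float) -> float:
    """Evaluate one segment's quadratic at the given height (metres)."""
    _check_height(height_m)
    a, b, c = model.coeffs[Segment(segment)]
    return a * height_m**2 + b * height_m + c


def composite_lengths(model: LengthModel, height_m: float) -> CompositeLengths:
    """Hand and heart-to-hallux path lengths for both sides."""
    _check_height(height_m)
    seg = {s: segment_length(model, s, height_m) for s in Segment}
    return CompositeLengths(
        ra_m=seg[Segment.RA],
        la_m=seg[Segment.LA],
        arf_m=seg[Segment.AR] + seg[Segment.PA],
        alf_m=seg[Segment.AL] + seg[Segment.PA],
    )


def fit_length_model(
    heights: Sequence[float],
    lengths: Mapping[Segment, Sequence[float]],
) -> tuple[LengthModel, dict[Segment, float]]:
    """Ordinary least-squares quadratic refit, one fit per segment.

    Parameters
    ----------
    heights : heights in metres (shared across segments).
    lengths : measured segment lengths in metres, same length as
        ``heights`` for each provided segment.

    Returns the fitted model (segments not provided keep the defaults)
    and the per-segment residual sum of squares.
    """
    h = np.asarray(heights, dtype=float)
    if np.unique(h).size < 3:
        raise RankError(
            f"need >= 3 distinct heights to fit a quadratic, got {np.unique(h).size}"
        )
    coeffs = dict(DEFAULT_COEFFS)
    rss: dict[Segment, float] = {}
    for seg_key, y in lengths.items():
        seg = Segment(seg_key)
        y = np.asarray(y, dtype=float)
        if y.size != h.size:
            raise RankError(f"segment {seg.value}: {y.size} lengths for {h.size} heights")
        abc = np.polyfit(h, y, 2)
        coeffs[seg] = tuple(float(v) for v in abc)
        rss[seg] = float(np.sum((np.polyval(abc, h) - y) ** 2))
    return LengthModel(coeffs), rss
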