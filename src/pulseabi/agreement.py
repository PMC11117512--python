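"""Clinical agreement statistics for the 22-subject validation table.

The system's ABI is compared against the Doppler/sphygmomanometer
reference with three complementary views:

* tolerance-band concordance — how many paired measurements differ by
  at most +/-0.1, the band clinicians treat as diagnostically neutral;
* mean absolute error (MAE) of the paired differences;
* Bland-Altman analysis — bias (mean difference) and limits of
  agreement at mean +/- 1.96 * SD of the differences.

The reference method could not quantify subject 11 (incompressible,
calcified arteries, reading ">1.30"); those entries participate
numerically as 1.30 and are flagged as censored.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np

from .errors import EmptyInputError, FixtureError, InsufficientDataError
from .signals import SubjectRecord, load_table1

DEFAULT_TOL = 0.1


class SdMode(str, Enum):
    POPULATION = "POPULATION"  # divisor n
    SAMPLE = "SAMPLE"  # divisor n - 1


@dataclass(frozen=True)
class PairedMeasurements:
    """Aligned reference vs test ABI readings."""

    labels: tuple
    reference: np.ndarray
    test: np.ndarray

    def __post_init__(self):
        ref = np.asarray(self.reference, dtype=float)
        tst = np.asarray(self.test, dtype=float)
        if not (len(self.labels) == ref.size == tst.size):
            raise EmptyInputError("labels, reference and test must have equal lengths")
        if not (np.all(np.isfinite(ref)) and np.all(np.isfinite(tst))):
            raise EmptyInputError("paired measurements must be finite")
        object.__setattr__(self, "labels", tuple(self.labels))
        object.__setattr__(self, "reference", ref)
        object.__setattr__(self, "test", tst)

    @property
    def diffs(self) -> np.ndarray:
        return self.reference - self.test

    @property
    def means(self) -> np.ndarray:
        return (self.reference + self.test) / 2.0

    def __len__(self) -> int:
        return self.reference.size


@dataclass(frozen=True)
class BlandAltmanResult:
    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    n: int
    n_within: int
    sd_mode: SdMode

    def to_dict(self) -> dict:
        d = {
            "mean_diff": self.mean_diff,
            "sd_diff": self.sd_diff,
            "loa_low": self.loa_low,
            "loa_high": self.loa_high,
            "n": self.n,
            "n_within": self.n_within,
            "sd_mode": self.sd_mode.value,
        }
        return d


def mae(diffs: Sequence[float]) -> float:
    """Mean absolute value of paired differences."""
    d = np.asarray(diffs, dtype=float)
    if d.size == 0:
        raise EmptyInputError("cannot compute MAE of an empty sequence")
    return float(np.mean(np.abs(d)))


def concordance(diffs: Sequence[float], tol: float = DEFAULT_TOL) -> tuple[int, float]:
    """Count and percentage of differences with |diff| <= tol."""
    d = np.asarray(diffs, dtype=float)
    if d.size == 0:
        raise EmptyInputError("cannot compute concordance of an empty sequence")
    if tol <= 0:
        raise EmptyInputError(f"tolerance must be positive, got {tol}")
    count = int(np.sum(np.abs(d) <= tol))
    return count, 100.0 * count / d.size


def bland_altman(pairs: PairedMeasurements, sd_mode: SdMode = SdMode.POPULATION) -> BlandAltmanResult:
    """Bias and limits of agreement (mean +/- 1.96 SD of the differences).

    ``n_within`` counts differences inside the closed limits interval.
    """
    sd_mode = SdMode(sd_mode)
    d = pairs.diffs
    if d.size < 3:
        raise InsufficientDataError(f"Bland-Altman needs n >= 3, got {d.size}")
    mean_diff = float(np.mean(d))
    sd = float(np.std(d, ddof=0 if sd_mode is SdMode.POPULATION else 1))
    lo, hi = mean_diff - 1.96 * sd, mean_diff + 1.96 * sd
    n_within = int(np.sum((d >= lo) & (d <= hi)))
    return BlandAltmanResult(mean_diff, sd, lo, hi, int(d.size), n_within, sd_mode)


def _pairs(records: Sequence[SubjectRecord], side: str) -> PairedMeasurements:
    if side == "right":
        return PairedMeasurements(
            tuple(f"s{r.subject_id}-R" for r in records),
            [r.abi_trad_right for r in records],
            [r.abi_sys_right for r in records],
        )
    return PairedMeasurements(
        tuple(f"s{r.subject_id}-L" for r in records),
        [r.abi_trad_left for r in records],
        [r.abi_sys_left for r in records],
    )


def _both_sides(records: Sequence[SubjectRecord]) -> PairedMeasurements:
    right, left = _pairs(records, "right"), _pairs(records, "left")
    return PairedMeasurements(
        right.labels + left.labels,
        np.concatenate([right.reference, left.reference]),
        np.concatenate([right.test, left.test]),
    )


def _summary(pairs: PairedMeasurements, tol: float) -> dict:
    count, pct = concordance(pairs.diffs, tol)
    return {
        "n": len(pairs),
        "mae": mae(pairs.diffs),
        "concordance_count": count,
        "concordance_pct": pct,
    }


def validation_report(
    records: Optional[Sequence[SubjectRecord]] = None,
    tol: float = DEFAULT_TOL,
) -> dict:
    """Per-side and per-sex agreement statistics over the validation table.

    Returns a JSON-serialisable dict with MAE, tolerance-band
    concordance and Bland-Altman results (both SD conventions) for each
    side, plus sex-stratified summaries.
    """
    if records is None:
        records = load_table1()
    if len(records) != 22:
        raise FixtureError(f"validation table must have 22 records, got {len(records)}")

    females = [r for r in records if r.sex == "F"]
    males = [r for r in records if r.sex == "M"]

    report: dict = {"n_subjects": len(records), "tolerance": tol, "sides": {}, "by_sex": {}}
    for side in ("right", "left"):
        pairs = _pairs(records, side)
        entry = _summary(pairs, tol)
        entry["bland_altman"] = {
            mode.value.lower(): bland_altman(pairs, mode).to_dict() for mode in SdMode
        }
        report["sides"][side] = entry
    report["overall"] = _summary(_both_sides(records), tol)
    for sex_name, group in (("female", females), ("male", males)):
        report["by_sex"][sex_name] = {
            "right": _summary(_pairs(group, "right"), tol),
            "left": _summary(_pairs(group, "left"), tol),
            "overall": _summary(_both_sides(group), tol),
        }
    report["censored_subjects"] = [r.subject_id for r in records if r.trad_censored]
    return report


def render_report(report: dict) -> str:
    """Plain-text rendering of ``validation_report`` output."""
    lines = [
        f"Validation over {report['n_subjects']} subjects "
        f"(tolerance band +/-{report['tolerance']})",
        "",
        f"{'group':<16}{'n':>4}{'MAE':>10}{'within':>8}{'pct':>9}",
    ]

    def row(name: str, s: dict) -> str:
        return (
            f"{name:<16}{s['n']:>4}{s['mae']:>10.4f}"
            f"{s['concordance_count']:>8}{s['concordance_pct']:>8.2f}%"
        )

    lines.append(row("overall", report["overall"]))
    for side in ("right", "left"):
        lines.append(row(side, report["sides"][side]))
    for sex in ("female", "male"):
        for scope in ("right", "left", "overall"):
            lines.append(row(f"{sex} {scope}", report["by_sex"][sex][scope]))
    lines.append("")
    for side in ("right", "left"):
        ba = report["sides"][side]["bland_altman"]["population"]
        lines.append(
            f"Bland-Altman {side}: bias {ba['mean_diff']:+.4f}, "
            f"LoA [{ba['loa_low']:+.4f}, {ba['loa_high']:+.4f}], "
            f"{ba['n_within']}/{ba['n']} within"
        )
    if report["censored_subjects"]:
        ids = ", ".join(str(i) for i in report["censored_subjects"])
        lines.append(f"Censored reference readings (>1.30, entered as 1.30): subject {ids}")
    return "\n".join(lines)


def bland_altman_plot(pairs: PairedMeasurements, path, sd_mode: SdMode = SdMode.POPULATION, title: str = ""):
    """Write a Bland-Altman plot (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    res = bland_altman(pairs, sd_mode)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(pairs.means, pairs.diffs, color="tab:blue", s=25)
    ax.axhline(res.mean_diff, color="red", label=f"bias {res.mean_diff:+.3f}")
    for y in (res.loa_low, res.loa_high):
        ax.axhline(y, color="black", linestyle="--")
    ax.set_xlabel("mean of methods (ABI)")
    ax.set_ylabel("reference - system (ABI)")
    if title:
        ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return res
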