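"""Pulse wave velocity and ankle-brachial index.

PWV is arterial path length over pulse transit time (m/s). The ABI of a
side is the ratio of the foot PWV to the hand PWV,

    ABI = PWV_foot / PWV_hand = (L_foot / PTT_foot) / (L_hand / PTT_hand),

computed per beat and averaged arithmetically over a 30-second window.
A ratio near 1 indicates comparable wave speeds to both extremities; a
reduced ratio is the screening signal for peripheral artery disease.

``process_session`` chains the whole pipeline: mains removal, wavelet
reconstruction/denoising, polarity correction, R/S landmarking,
per-beat transit times, height-derived path lengths, per-beat PWV and
ABI, and the windowed summary.
"""

from __future__ import annotations

import json
from contextlib import contextmanager
from dataclasses import asdict, dataclass
from typing import Optional, Sequence

import numpy as np

from . import beats as beats_mod
from . import preprocess as pre
from .anatomy import LengthModel, composite_lengths
from .beats import BeatSeries, DetectorSettings
from .errors import DomainError, InsufficientDurationError, StageError
from .preprocess import FilterSettings, Polarity
from .signals import RecordingSession, Side

PWV_PLAUSIBLE_MS = (0.5, 30.0)  # physiological sanity band, m/s
MIN_BEATS_REPORTABLE = 10


@dataclass(frozen=True)
class SideResult:
    """Per-side summary of one recording session."""

    side: Side
    hrv_bpm: float
    mean_ptt_hand_s: float
    mean_ptt_foot_s: float
    pwv_hand_ms: float
    pwv_foot_ms: float
    abi: float
    n_beats_used: int
    window_s: float = 30.0

    @property
    def reportable(self) -> bool:
        return self.n_beats_used >= MIN_BEATS_REPORTABLE

    @property
    def pwv_plausible(self) -> bool:
        lo, hi = PWV_PLAUSIBLE_MS
        return lo < self.pwv_hand_ms < hi and lo < self.pwv_foot_ms < hi

    def to_json(self) -> str:
        d = asdict(self)
        d["side"] = self.side.value
        d["reportable"] = self.reportable
        d["pwv_plausible"] = self.pwv_plausible
        return json.dumps(d, indent=2)


def pwv(length_m: float, ptt_s: float) -> float:
    """Pulse wave velocity in m/s: path length over transit time."""
    if length_m <= 0 or ptt_s <= 0:
        raise DomainError(f"length {length_m} m and PTT {ptt_s} s must both be positive")
    return length_m / ptt_s


def abi_per_beat(pwv_foot: float, pwv_hand: float) -> float:
    """Single-beat ABI: foot PWV over hand PWV."""
    if pwv_foot <= 0 or pwv_hand <= 0:
        raise DomainError(f"PWVs must be positive, got foot={pwv_foot}, hand={pwv_hand}")
    return pwv_foot / pwv_hand


def _window_mask(times: np.ndarray, window_s: float, start_offset_s: float) -> np.ndarray:
    t0 = times[0] + start_offset_s
    return (times >= t0) & (times <= t0 + window_s)


def abi_summary(
    per_beat_abi: Sequence[float],
    beat_times_s: Sequence[float],
    window_s: float = 30.0,
    start_offset_s: float = 0.0,
) -> tuple[float, int]:
    """Arithmetic mean of per-beat ABI over one contiguous window.

    The default window is the first ``window_s`` seconds of usable
    beats; ``start_offset_s`` shifts it for operator-style interval
    selection. Returns (mean ABI, number of beats averaged).
    """
    abi = np.asarray(per_beat_abi, dtype=float)
    t = np.asarray(beat_times_s, dtype=float)
    if abi.size != t.size:
        raise DomainError(f"{abi.size} ABI values for {t.size} beat times")
    if abi.size == 0 or t[-1] - t[0] < window_s:
        span = 0.0 if abi.size == 0 else t[-1] - t[0]
        raise InsufficientDurationError(
            f"usable beats span {span:.1f} s < required window of {window_s} s"
        )
    mask = _window_mask(t, window_s, start_offset_s)
    if not mask.any():
        raise InsufficientDurationError("no beats inside the selected window")
    return float(np.mean(abi[mask])), int(mask.sum())


@contextmanager
def _stage(name: str):
    try:
        yield
    except Exception as exc:  # noqa: BLE001 — re-raise with stage context
        raise StageError(name, exc) from exc


def preprocess_session(
    session: RecordingSession,
    filter_settings: FilterSettings = FilterSettings(),
) -> tuple:
    """Denoise all three channels and correct ECG polarity.

    Returns (ecg_reconstructed, ecg_mains_filtered, ppg_hand, ppg_foot);
    both ECG variants are polarity-corrected. Detection runs on the
    wavelet reconstruction, timing refinement on the mains-filtered
    trace.
    """
    with _stage("powerline removal"):
        ecg_raw = pre.remove_powerline(session.ecg, filter_settings)
        ppg_hand = pre.remove_powerline(session.ppg_hand, filter_settings)
        ppg_foot = pre.remove_powerline(session.ppg_foot, filter_settings)
    with _stage("ECG wavelet reconstruction"):
        ecg = pre.ecg_wavelet_reconstruct(ecg_raw, filter_settings)
    with _stage("polarity correction"):
        if pre.detect_polarity(ecg) is Polarity.NEGATIVE:
            ecg = ecg.with_values(-ecg.values)
            ecg_raw = ecg_raw.with_values(-ecg_raw.values)
    with _stage("PPG wavelet denoising"):
        ppg_hand = pre.ppg_wavelet_denoise(ppg_hand, filter_settings)
        ppg_foot = pre.ppg_wavelet_denoise(ppg_foot, filter_settings)
    return ecg, ecg_raw, ppg_hand, ppg_foot


def process_session(
    session: RecordingSession,
    filter_settings: FilterSettings = FilterSettings(),
    detector_settings: DetectorSettings = DetectorSettings(),
    length_model: Optional[LengthModel] = None,
    window_s: float = 30.0,
    window_start_s: float = 0.0,
) -> SideResult:
    """End-to-end per-side pipeline from raw channels to an ABI summary.

    Deterministic given the session and settings. Beats missing either
    systolic point are excluded; the summary requires the remaining
    beats to span at least ``window_s`` seconds.
    """
    model = length_model or LengthModel.default()
    fs = session.fs

    ecg, ecg_raw, ppg_hand, ppg_foot = preprocess_session(session, filter_settings)

    with _stage("landmark detection"):
        r = beats_mod.locate_r_peaks(ecg, ecg_raw, detector_settings)
        s_hand = beats_mod.detect_s_peaks(ppg_hand, r, detector_settings)
        s_foot = beats_mod.detect_s_peaks(ppg_foot, r, detector_settings)

    with _stage("transit times"):
        usable = [
            (ri, sh, sf)
            for ri, sh, sf in zip(r, s_hand, s_foot)
            if sh is not None and sf is not None
        ]
        beat_times = np.array([ri / fs for ri, _, _ in usable])
        ptt_h = np.array([(sh - ri) / fs for ri, sh, _ in usable])
        ptt_f = np.array([(sf - ri) / fs for ri, _, sf in usable])

    with _stage("hemodynamics"):
        lengths = composite_lengths(model, session.height_m)
        l_hand = lengths.hand_m(session.side)
        l_foot = lengths.foot_m(session.side)
        per_beat = np.array(
            [abi_per_beat(pwv(l_foot, tf), pwv(l_hand, th)) for th, tf in zip(ptt_h, ptt_f)]
        )

    with _stage("ABI summary"):
        abi, n_used = abi_summary(per_beat, beat_times, window_s, window_start_s)
        mask = _window_mask(beat_times, window_s, window_start_s)
        mean_ptt_h = float(np.mean(ptt_h[mask]))
        mean_ptt_f = float(np.mean(ptt_f[mask]))

    with _stage("heart rate"):
        hr = beats_mod.hrv_bpm(r, fs)

    return SideResult(
        side=session.side,
        hrv_bpm=hr,
        mean_ptt_hand_s=mean_ptt_h,
        mean_ptt_foot_s=mean_ptt_f,
        pwv_hand_ms=pwv(l_hand, mean_ptt_h),
        pwv_foot_ms=pwv(l_foot, mean_ptt_f),
        abi=abi,
        n_beats_used=n_used,
        window_s=window_s,
    )
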