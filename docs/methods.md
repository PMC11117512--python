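# Methods

## Model

The package estimates the ankle–brachial index of one body side as a ratio of
pulse wave velocities,

    ABI = PWV_foot / PWV_hand
        = (L_foot / PTT_foot) / (L_hand / PTT_hand),

where each pulse transit time (PTT) is the delay from a chest-ECG R-peak to
the systolic peak of a PPG at a distal site (index fingertip, hallux), and
each path length L is a quadratic in subject height (see below). The ratio is
computed per beat — hand-beat and foot-beat are paired through the same
R-peak — and the reported ABI is the arithmetic mean over a 30-second window
of usable beats (beats missing either systolic point are dropped, not
interpolated). Averaging per-beat ratios rather than ratioing averaged PWVs
follows the per-measurement-point definition of the quantity; for the small
beat-to-beat PTT variations seen in practice the two differ by well under a
percent.

Assumptions worth making explicit:

* The three channels are clock-synchronised. No synchronisation protocol is
  modelled; an optional per-channel `t0` offset allows manual alignment.
* The pre-ejection period (R-peak to actual aortic valve opening) is part of
  both transit times and is not subtracted. It partially cancels in the
  ratio but biases individual PWVs low; the PWV values are therefore
  "R-peak-referenced" velocities, not gold-standard stiffness PWVs.
* Path lengths depend on height alone — no sex, age or side-specific
  anthropometry beyond the five fitted segments.

## Arterial length model

Five quadratic segment equations (metres as a function of height H in
metres): RA/LA heart→index finger, AR/AL heart→heel, PA heel→hallux;
heart→hallux is AR+PA (right) or AL+PA (left). The default coefficients are
the published fit to surface measurements of 35 adults; that raw dataset is
not available, so `fit_length_model` (ordinary least squares per segment) is
validated on model-generated data: noiseless data reproduce the coefficients
to 1e-9, and 5 mm measurement noise at n=35 keeps predicted lengths within
1 cm over the adult height range.

Evaluation is guarded to H ∈ [1.0, 2.5] m; the quadratics turn non-physical
under extrapolation. One caveat found by direct evaluation: the PA
quadratic's vertex lies at H = 1.806 m, so the plantar segment *decreases*
slightly for taller subjects. Lengths remain positive and the composite
heart→hallux lengths remain monotone; the behaviour is inherited from the
published coefficients and is documented rather than corrected.

## Preprocessing

**Powerline removal.** Default is an IIR notch at 50 Hz (quality factor 30)
applied forward–backward (zero phase), so landmark times are not shifted.
Measured steady-state attenuation at 50 Hz exceeds 60 dB while a 1 Hz tone
passes within 1%. A literal 50 Hz high-pass is selectable
(`mode=LITERAL_HIGHPASS`) for fidelity with hardware chains that apply one,
but it removes nearly all QRS energy at fs = 200 Hz and is not recommended.
Forward–backward filtering leaves settling transients at the record ends;
the beat detector therefore ignores candidates within 0.25 s of either end
(`edge_guard_s`), and the notch is padded with 3 s of reflected signal so a
high-Q ring-down does not leak mains back in at the edges.

**ECG.** Four-level `sym4` decomposition; the signal is rebuilt from detail
levels 2 and 4 only (level 2, 25–50 Hz at fs = 200, carries the QRS edge;
level 4, 6.25–12.5 Hz, keeps low-frequency wave shape so weak or inverted
complexes remain recognisable; the discarded approximation removes baseline
wander). Boundary handling uses periodization: it makes the transform
orthogonal, so keep-subset reconstruction is an exact projection —
idempotent to machine precision and energy-non-increasing — which symmetric
extension does not satisfy (boundary errors ~0.18 on a 90 s record).

Polarity is decided by the sign of the third central moment of the
reconstructed trace: a sparse upright spike train is strongly right-skewed,
an inverted one left-skewed, regardless of spike duty cycle and of the
side-lobes band-limited reconstruction adds. (A percentile-asymmetry rule
was evaluated first and misclassifies upright trains: the zero-mean
reconstruction has wider negative side-lobes than positive peak mass at the
5th/95th percentile level.) A constant signal raises an error.

**PPG.** Stationary (undecimated) `sym4` decomposition to 5 levels; detail
coefficients are soft-thresholded at the universal threshold
σ·sqrt(2·ln N), σ = median(|cD1|)/0.6745, then inverted. The stationary
transform matters here: systolic-peak *timing* is the deliverable, and
decimated shrinkage leaves pseudo-Gibbs wiggles around each pulse crest that
drag the argmax around by several samples (measured: sd ≈ 3.7 samples
decimated vs 0.5 samples stationary at 10 dB SNR). A noiseless record gives
σ̂ = 0 and passes through unchanged.

## Landmark detection

**R-peaks** are found in three stages, all deterministic:

1. *Detection* on the detail-band reconstruction: local maxima exceeding
   0.6 × the 99th percentile of |signal| in a surrounding 2 s window,
   thinned by non-maximum suppression with a 0.25 s refractory period
   (ties resolved toward the earlier sample).
2. *Refinement* on the mains-filtered trace: the decimated reconstruction is
   shift-variant (apparent peak position depends on the beat's phase
   relative to the decimation grid), so each index moves to the argmax
   within ±0.125 s after zero-phase smoothing with a 10 ms Gaussian — a
   matched filter at the QRS-apex scale. Refined peaks whose amplitude falls
   below 0.6 × the median refined amplitude are discarded as noise
   (sinus R-wave amplitude varies far less beat to beat).
3. *Search-back*: any R-R gap longer than 1.7 × the median R-R is re-searched
   for a peak above the same amplitude floor, repeating until stable — the
   classical secondary-threshold pass of QRS detectors.

Measured on synthetic ground truth over 20 seeds: worst timing error 0.5
samples clean / 0.91 samples at 10 dB SNR with full-amplitude 50 Hz hum,
recall ≥ 0.99.

**S-points.** For each R-peak, the systolic peak is the highest interior
local maximum of the denoised PPG in the window from R + 0.05 s (skipping the
electrically coincident artifact region) to the next R-peak, but never more
than one median R-R after R — the beat period bounds where the pulse can
fall, so a missed beat cannot hand a window the next beat's pulse. Windows
with no interior maximum (flat signal) mark the beat missing.

**HRV** is reported as 60 / mean(R-R) in beats per minute.

## Synthetic data generator

The pipeline exploits only landmark times, so the generator favours simple
analytically peaked kernels over morphological realism: Gaussian QRS bumps
(half-width 0.02 s, optional negative polarity, optional T-wave bump) and
raised-cosine systolic pulses (0.3 s support) delayed by the configured
per-limb transit times. Defaults encode the reference study condition:
fs = 200 Hz, 90 s per side, 60 bpm with 0.02 s R-R jitter (clipped at 3 SD to
respect the refractory bound), PTTh = 0.20 s, PTTf = 0.30 s, all confounders
off. Confounders are opt-in: 50 Hz mains, sinusoidal baseline wander
(0.2 Hz), and white noise either as an explicit sigma or via `snr_db`, the
standard power ratio (sigma = RMS(clean)/10^(SNR/20), per channel). The
"noisy" test condition is mains at full QRS amplitude plus 10 dB SNR noise.

What the generator does **not** emulate — and hence what passing tests do not
establish about real data: PPG morphology (dicrotic notch, amplitude drift,
motion artifacts with pulse-like shape), ectopy and arrhythmia, PTT drift
within a session, sensor saturation, and inter-device clock skew. Results on
synthetic data bound algorithmic error only, not physiological validity;
the clinical evidence lives in the embedded 22-subject table.

## Agreement statistics

Paired traditional-vs-system ABIs (2 sides × 22 subjects). Reported per side
and per sex: mean absolute error of the differences, count/percentage within
the ±0.1 clinical tolerance band (closed interval; no table value sits on the
boundary), and Bland–Altman bias with limits of agreement at mean ± 1.96·SD.
Both SD conventions (population n, sample n−1) are computed because the
source does not state which was used; the headline count — 21 of 22 left-side
differences within the limits — holds under both. Subject 11's traditional
readings (">1.30", incompressible arteries) enter numerically as 1.30 and are
flagged as censored.

Two published right-side/male statistics are *not* reproducible from the
printed 3-decimal table and are deliberately not asserted: the right-side
concordance count (printed values give 16, not 17 — subject 13's
|1.18 − 1.066| = 0.114 is the borderline pair; unrounded system values were
presumably used) and the male MAE (table gives 0.1137 vs published 0.1129).
The published RMSE figures (0.3396/0.2991) match no definition computable
from the table (RMS of differences ≈ 0.13 per side) and are excluded.

## Numerical and design choices

* Sample indexing is 0-based; time of sample i is t0 + i/fs; all intervals in
  seconds. Default fs = 200 Hz.
* Detector thresholds (0.6 fraction, 0.25 s refractory, 2 s reference window,
  0.05 s minimum R→S delay) are package defaults chosen on physiological
  grounds, all overridable via `DetectorSettings`/JSON config.
* ABI summary window: first 30 s of usable beats by default, with a start
  offset for operator-style interval selection; at least 10 beats are
  required for a result flagged `reportable`.
* PWV values outside 0.5–30 m/s are flagged implausible but still reported.
* Degenerate inputs raise typed errors naming the failing stage
  (`StageError` wraps the pipeline position).
* Problem sizes used in the test suite and acceptance script — 90 s sessions,
  3×3 transit-time grids, single seeds per cell — keep full runs under a
  minute while leaving every pipeline stage exercised end to end.

## Known limitations

* The ABI here is a PWV ratio, not a pressure ratio; its diagnostic
  thresholds are not interchangeable with cuff-Doppler ABI cut-offs without
  clinical calibration.
* Height-only path lengths ignore limb-proportion variation; errors in
  L_foot/L_hand translate linearly into ABI bias for an individual.
* The R-peak amplitude-consistency and search-back rules assume sinus
  rhythm; frequent ectopy would defeat both.
* No motion-artifact handling beyond wavelet shrinkage.
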