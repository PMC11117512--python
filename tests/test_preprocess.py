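import numpy as np
import pytest

from pulseabi import (
    Channel,
    FilterSettings,
    MainsMode,
    Polarity,
    SampledSignal,
    Side,
    SynthSettings,
    detect_polarity,
    ecg_wavelet_reconstruct,
    generate_session,
    ppg_wavelet_denoise,
    remove_powerline,
)
from pulseabi.errors import ConfigError, PolarityError, SignalLengthError

from conftest import sine_signal


def rms(x):
    return float(np.sqrt(np.mean(np.asarray(x) ** 2)))


def steady_state(values, fs=200.0, settle_s=1.0):
    """Drop the filter settling region at both record ends."""
    k = int(settle_s * fs)
    return np.asarray(values)[k:-k]


class TestRemovePowerline:
    def test_mains_tone_attenuated_at_least_20db(self):
        sig = sine_signal(50.0)
        out = remove_powerline(sig)
        assert rms(steady_state(out.values)) <= 0.1 * rms(steady_state(sig.values))

    def test_physiological_band_passes(self):
        sig = sine_signal(1.0)
        out = remove_powerline(sig)
        assert abs(rms(out.values) - rms(sig.values)) <= 0.01 * rms(sig.values)

    def test_sub_notch_component_barely_touched(self):
        # < 1 dB at 40 Hz: the notch must be narrow
        sig = sine_signal(40.0)
        out = remove_powerline(sig)
        assert rms(out.values) >= 10 ** (-1 / 20) * rms(sig.values)

    def test_zero_in_zero_out(self):
        sig = SampledSignal(np.zeros(1000), Channel.ECG, Side.RIGHT)
        assert np.allclose(remove_powerline(sig).values, 0.0)

    def test_zero_phase_landmark_preserved(self):
        # a clean pulse's argmax moves by <= 1 sample through the notch
        t = np.arange(2000) / 200.0
        pulse = np.exp(-((t - 5.0) ** 2) / (2 * 0.02**2))
        sig = SampledSignal(pulse, Channel.ECG, Side.RIGHT)
        out = remove_powerline(sig)
        assert abs(int(np.argmax(out.values)) - int(np.argmax(pulse))) <= 1

    def test_literal_highpass_mode_kills_low_frequencies(self):
        settings = FilterSettings(mode=MainsMode.LITERAL_HIGHPASS)
        low = remove_powerline(sine_signal(5.0), settings)
        assert rms(low.values) < 0.05 * rms(sine_signal(5.0).values)

    def test_rate_below_nyquist_rejected(self):
        sig = SampledSignal(np.zeros(100), Channel.ECG, Side.RIGHT, fs=80.0)
        with pytest.raises(ConfigError):
            remove_powerline(sig)


class TestEcgWaveletReconstruct:
    def test_projection_is_idempotent(self):
        rng = np.random.default_rng(0)
        sig = SampledSignal(rng.normal(size=4096), Channel.ECG, Side.RIGHT)
        once = ecg_wavelet_reconstruct(sig)
        twice = ecg_wavelet_reconstruct(once)
        assert np.max(np.abs(twice.values - once.values)) < 1e-9

    def test_energy_never_increases(self):
        rng = np.random.default_rng(1)
        sig = SampledSignal(rng.normal(size=4096), Channel.ECG, Side.RIGHT)
        out = ecg_wavelet_reconstruct(sig)
        assert np.sum(out.values**2) <= np.sum(sig.values**2) + 1e-9

    def test_discards_unkept_detail_level(self):
        # build a signal living purely in detail level 3, which is not kept
        import pywt

        rng = np.random.default_rng(2)
        n = 4096
        coeffs = pywt.wavedec(rng.normal(size=n), "sym4", level=4, mode="periodization")
        only_d3 = [np.zeros_like(c) for c in coeffs]
        only_d3[2] = coeffs[2]
        x = pywt.waverec(only_d3, "sym4", mode="periodization")[:n]
        sig = SampledSignal(x, Channel.ECG, Side.RIGHT)
        out = ecg_wavelet_reconstruct(sig)
        corr = np.corrcoef(out.values, x)[0, 1] if np.any(out.values) else 0.0
        assert abs(corr) < 0.5

    def test_baseline_wander_removed(self):
        settings = SynthSettings(seed=3, wander_amp=5.0, wander_hz=0.2)
        session, _ = generate_session(settings, 1.7)
        out = ecg_wavelet_reconstruct(session.ecg)
        # residual baseline measured away from QRS complexes
        assert np.mean(np.abs(np.median(out.values))) < 0.05
        assert rms(out.values) < rms(session.ecg.values) * 0.5

    def test_zero_in_zero_out(self):
        sig = SampledSignal(np.zeros(256), Channel.ECG, Side.RIGHT)
        assert np.allclose(ecg_wavelet_reconstruct(sig).values, 0.0)

    def test_too_short_rejected(self):
        sig = SampledSignal(np.ones(8), Channel.ECG, Side.RIGHT)
        with pytest.raises(SignalLengthError):
            ecg_wavelet_reconstruct(sig)


class TestPolarity:
    def test_upright_train_positive(self, clean_session):
        session, _, _ = clean_session
        ecg = ecg_wavelet_reconstruct(remove_powerline(session.ecg))
        assert detect_polarity(ecg) is Polarity.POSITIVE

    def test_antisymmetry(self, clean_session):
        session, _, _ = clean_session
        ecg = ecg_wavelet_reconstruct(remove_powerline(session.ecg))
        flipped = ecg.with_values(-ecg.values)
        assert detect_polarity(flipped) is Polarity.NEGATIVE

    def test_negative_qrs_generator(self):
        session, _ = generate_session(SynthSettings(seed=4, qrs_polarity="NEGATIVE"), 1.7)
        ecg = ecg_wavelet_reconstruct(remove_powerline(session.ecg))
        assert detect_polarity(ecg) is Polarity.NEGATIVE

    def test_constant_signal_rejected(self):
        sig = SampledSignal(np.zeros(100), Channel.ECG, Side.RIGHT)
        with pytest.raises(PolarityError):
            detect_polarity(sig)


class TestPpgDenoise:
    def test_noise_reduced_relative_to_clean_reference(self):
        clean_settings = SynthSettings(seed=5)
        clean, _ = generate_session(clean_settings, 1.7)
        noisy, _ = generate_session(SynthSettings(seed=5, snr_db=10.0), 1.7)
        out = ppg_wavelet_denoise(noisy.ppg_hand)
        err_in = rms(noisy.ppg_hand.values - clean.ppg_hand.values)
        err_out = rms(out.values - clean.ppg_hand.values)
        assert err_out < err_in

    def test_clean_train_nearly_unchanged(self, clean_session):
        session, _, _ = clean_session
        out = ppg_wavelet_denoise(session.ppg_hand)
        corr = np.corrcoef(out.values, session.ppg_hand.values)[0, 1]
        assert corr >= 0.99

    def test_zero_in_zero_out(self):
        sig = SampledSignal(np.zeros(256), Channel.PPG_HAND, Side.RIGHT)
        assert np.allclose(ppg_wavelet_denoise(sig).values, 0.0)

    def test_length_preserved_on_non_dyadic_input(self):
        rng = np.random.default_rng(6)
        sig = SampledSignal(rng.normal(size=1001), Channel.PPG_HAND, Side.RIGHT)
        assert len(ppg_wavelet_denoise(sig)) == 1001
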