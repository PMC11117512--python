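import numpy as np
import pytest
from hypothesis import given, settings as hyp_settings
from hypothesis import strategies as st

from pulseabi import (
    SynthSettings,
    abi_per_beat,
    abi_summary,
    composite_lengths,
    generate_session,
    process_session,
    pwv,
    LengthModel,
)
from pulseabi.errors import DomainError, InsufficientDurationError

# closed-form study condition: H=1.7, PTTh=0.20 s, PTTf=0.30 s, right side
TRUE_ABI_REF = (1.508354 / 0.30) / (0.909693 / 0.20)  # = 1.10539...


class TestPwv:
    def test_quotient(self):
        assert pwv(1.5084, 0.25) == pytest.approx(6.0336)

    def test_identity(self):
        assert pwv(1.0, 1.0) == 1.0

    @pytest.mark.parametrize("length,ptt", [(1.0, 0.0), (0.0, 1.0), (-1.0, 0.2)])
    def test_domain_errors(self, length, ptt):
        with pytest.raises(DomainError):
            pwv(length, ptt)


class TestAbiPerBeat:
    def test_equal_pwvs_give_unity(self):
        assert abi_per_beat(7.0, 7.0) == 1.0

    def test_scaling(self):
        assert abi_per_beat(1.2 * 5.0, 5.0) == pytest.approx(1.2)

    def test_algebraic_identity_with_lengths_and_ptts(self):
        # ABI == (L_foot * PTT_hand) / (L_hand * PTT_foot)
        comp = composite_lengths(LengthModel.default(), 1.7)
        via_pwv = abi_per_beat(pwv(comp.arf_m, 0.30), pwv(comp.ra_m, 0.20))
        direct = (comp.arf_m * 0.20) / (comp.ra_m * 0.30)
        assert abs(via_pwv - direct) < 1e-12
        assert via_pwv == pytest.approx(1.1053, abs=1e-4)

    @hyp_settings(max_examples=50, derandomize=True)
    @given(
        th=st.floats(min_value=0.06, max_value=0.59),
        tf=st.floats(min_value=0.06, max_value=0.59),
        k=st.floats(min_value=0.1, max_value=10.0),
    )
    def test_ptt_scale_invariance(self, th, tf, k):
        comp = composite_lengths(LengthModel.default(), 1.7)
        base = abi_per_beat(pwv(comp.arf_m, tf), pwv(comp.ra_m, th))
        scaled = abi_per_beat(pwv(comp.arf_m, k * tf), pwv(comp.ra_m, k * th))
        assert scaled == pytest.approx(base, rel=1e-9)
        # and each PWV scales by 1/k
        assert pwv(comp.arf_m, k * tf) == pytest.approx(pwv(comp.arf_m, tf) / k, rel=1e-9)


class TestAbiSummary:
    def test_mean_of_constant(self):
        times = np.arange(36.0)
        value, n = abi_summary(np.full(36, 1.1), times, window_s=30.0)
        assert value == pytest.approx(1.1)
        assert n == 31  # closed 30-s window starting at the first beat

    def test_equal_weighting(self):
        value, _ = abi_summary([1.0, 1.2], [0.0, 31.0], window_s=30.0)
        assert value == pytest.approx(1.0)  # only the first beat is inside the window
        value, _ = abi_summary([1.0, 1.2], [0.0, 30.0], window_s=30.0)
        assert value == pytest.approx(1.1)

    def test_short_span_rejected(self):
        with pytest.raises(InsufficientDurationError):
            abi_summary(np.ones(20), np.linspace(0, 20, 20), window_s=30.0)

    def test_start_offset_shifts_window(self):
        times = np.arange(80.0)
        values = np.where(times < 40, 1.0, 2.0)
        late, _ = abi_summary(values, times, window_s=30.0, start_offset_s=45.0)
        assert late == pytest.approx(2.0)


class TestProcessSession:
    def test_clean_session_recovers_closed_form_abi(self, clean_session):
        session, truth, _ = clean_session
        result = process_session(session)
        assert truth.true_abi == pytest.approx(TRUE_ABI_REF, abs=1e-6)
        assert result.abi == pytest.approx(TRUE_ABI_REF, abs=0.02)
        assert result.n_beats_used >= 10
        assert result.hrv_bpm == pytest.approx(60.0, abs=2.0)
        assert result.mean_ptt_hand_s == pytest.approx(0.20, abs=0.005)
        assert result.mean_ptt_foot_s == pytest.approx(0.30, abs=0.005)

    def test_noisy_session_within_wider_band(self, noisy_session):
        session, truth, _ = noisy_session
        result = process_session(session)
        assert result.abi == pytest.approx(truth.true_abi, abs=0.05)

    def test_short_recording_rejected(self):
        session, _ = generate_session(SynthSettings(seed=13, duration_s=20.0), 1.7)
        with pytest.raises(Exception) as excinfo:
            process_session(session)
        assert "ABI summary" in str(excinfo.value)

    def test_negative_polarity_handled(self):
        session, truth = generate_session(
            SynthSettings(seed=14, qrs_polarity="NEGATIVE"), 1.7
        )
        result = process_session(session)
        assert result.abi == pytest.approx(truth.true_abi, abs=0.02)

    def test_deterministic(self, clean_session):
        session, _, _ = clean_session
        a = process_session(session)
        b = process_session(session)
        assert a == b

    def test_result_serialises_to_json(self, clean_session):
        import json

        session, _, _ = clean_session
        result = process_session(session)
        payload = json.loads(result.to_json())
        assert payload["side"] == "RIGHT"
        assert payload["reportable"] is True
        assert payload["pwv_plausible"] is True
        assert 0 < payload["abi"] < 2
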