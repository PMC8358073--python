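"""Unit and property tests of the psychometric building blocks."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from avspeech import (
    AuditoryParams,
    GuessPolicy,
    LapseSet,
    ParticipantParams,
    StimulusCondition,
    Variant,
    VisualParams,
    apply_guess,
    apply_lapse,
    auditory_pf,
    mei,
    predict_recognition,
    prob_summation,
    visual_pf,
)
from avspeech.psychometrics import InvalidParameterError

AUD = AuditoryParams(threshold_db=-5.0, width_db=8.0)
VIS = VisualParams(threshold_px=18.0)

finite_snr = st.floats(-40.0, 40.0)
prob = st.floats(0.0, 1.0)


class TestAuditoryPF:
    def test_value_at_threshold_is_half(self):
        assert auditory_pf(AUD.threshold_db, AUD) == pytest.approx(0.5, abs=1e-12)

    @given(theta=st.floats(-30, 10), omega=st.floats(0.5, 30))
    def test_width_brackets_10_to_90_percent(self, theta, omega):
        """The 2*ln9/omega slope makes omega exactly the 10-90% range."""
        p = AuditoryParams(theta, omega)
        assert auditory_pf(theta + omega / 2, p) == pytest.approx(0.9, abs=1e-12)
        assert auditory_pf(theta - omega / 2, p) == pytest.approx(0.1, abs=1e-12)

    def test_lower_asymptote(self):
        assert auditory_pf(-1e6, AUD) == pytest.approx(0.0, abs=1e-12)

    def test_monotone_increasing_in_snr(self):
        grid = auditory_pf(np.linspace(-40, 40, 200), AUD)
        assert np.all(np.diff(grid) > 0)
        assert np.all((grid > 0) & (grid < 1))

    def test_nonpositive_width_rejected(self):
        with pytest.raises(InvalidParameterError):
            AuditoryParams(0.0, 0.0)


class TestVisualPF:
    def test_no_blur_gives_perfect_recognition(self):
        assert visual_pf(0.0, VIS) == 1.0

    def test_value_at_threshold_is_exp_minus_one(self):
        assert visual_pf(VIS.threshold_px, VIS) == pytest.approx(np.exp(-1), abs=1e-12)
        assert visual_pf(VIS.threshold_px, VIS) == pytest.approx(0.368, abs=5e-4)

    def test_extreme_blur_is_uninformative(self):
        # 70-px blur at the CI visual threshold: numerically negligible signal
        assert visual_pf(70.0, VisualParams(17.7)) < 1e-6

    def test_monotone_decreasing_in_blur(self):
        grid = visual_pf(np.linspace(0, 60, 200), VIS)
        assert np.all(np.diff(grid) < 0)

    def test_negative_blur_rejected(self):
        with pytest.raises(InvalidParameterError):
            visual_pf(-1.0, VIS)


class TestLapseAndGuess:
    @pytest.mark.parametrize(
        "f, lam, expected",
        [(1.0, 0.1, 0.9), (0.6, 0.0, 0.6), (0.787, 0.178, 0.647)],
    )
    def test_lapse_attenuation(self, f, lam, expected):
        assert apply_lapse(f, lam) == pytest.approx(expected, abs=5e-4)

    @pytest.mark.parametrize("psi, expected", [(0.0, 0.1), (1.0, 1.0), (0.5, 0.55)])
    def test_guess_floor(self, psi, expected):
        assert apply_guess(psi) == pytest.approx(expected, abs=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(InvalidParameterError):
            apply_lapse(1.2, 0.1)
        with pytest.raises(InvalidParameterError):
            apply_guess(-0.1)

    @given(f=prob, lam=prob)
    def test_lapse_never_increases_recognition(self, f, lam):
        assert apply_lapse(f, lam) <= f + 1e-15


class TestProbSummation:
    @pytest.mark.parametrize(
        "a, v, expected", [(0.5, 0.5, 0.75), (0.42, 0.0, 0.42), (0.647, 0.150, 0.700)]
    )
    def test_known_combinations(self, a, v, expected):
        assert prob_summation(a, v) == pytest.approx(expected, abs=5e-4)

    @given(a=prob, v=prob)
    def test_race_bounds(self, a, v):
        s = prob_summation(a, v)
        assert s >= max(a, v) - 1e-15
        assert s <= min(1.0, a + v) + 1e-15


class TestPredictRecognition:
    def test_variants_coincide_for_equal_task_lapses(self):
        params = ParticipantParams(
            AUD, VIS, LapseSet.vis_shared(0.2, 0.2, 0.4)
        )
        cond = StimulusCondition("AV", "divided", snr=-3.0, blur=10.0)
        assert predict_recognition(cond, params, "strict") == pytest.approx(
            predict_recognition(cond, params, "trade-off"), abs=1e-15
        )

    def test_visual_only_chain(self):
        """Unblurred video with a 0.46 visual lapse: 0.9 * 0.54 + 0.1."""
        params = ParticipantParams(AUD, VIS, LapseSet.vis_shared(0.1, 0.1, 0.46))
        cond = StimulusCondition("V", "focused", blur=0.0)
        assert predict_recognition(cond, params) == pytest.approx(0.586, abs=1e-12)

    def test_ci_group_means_brute_force(self, ci_group_params):
        """Chain the logistic, exponential, lapse, race and guess steps by hand."""
        p = ci_group_params
        f_a = 1.0 / (1.0 + np.exp(-(2 * np.log(9) / 10.4) * (0.0 - -3.1)))
        f_v = np.exp(-(20.0**2) / 17.7**2)
        psi_v = (1 - 0.46) * f_v
        expect = {}
        for variant, lam in [("trade-off", p.lapses.a_focused), ("strict", p.lapses.a_divided)]:
            psi_a = (1 - lam) * f_a
            expect[variant] = 0.9 * (psi_a + psi_v - psi_a * psi_v) + 0.1
        cond = StimulusCondition("AV", "divided", snr=0.0, blur=20.0)
        for variant in ("trade-off", "strict"):
            assert predict_recognition(cond, p, variant) == pytest.approx(
                expect[variant], abs=1e-12
            )
        assert expect["trade-off"] == pytest.approx(0.73, abs=0.005)
        assert expect["strict"] == pytest.approx(0.60, abs=0.005)

    def test_av_missing_dimension_rejected(self):
        with pytest.raises(InvalidParameterError):
            StimulusCondition("AV", "divided", snr=0.0, blur=None)
        with pytest.raises(InvalidParameterError):
            StimulusCondition("AV", "divided", snr=None, blur=10.0)

    @pytest.mark.parametrize("variant", ["strict", "trade-off"])
    def test_av_asymptotics_reduce_to_unisensory(self, ci_group_params, variant):
        """AV converges to V-only as the sound vanishes and to the auditory
        chain as the video blurs away."""
        p = ci_group_params
        av_no_sound = predict_recognition(
            StimulusCondition("AV", "divided", snr=-1e4, blur=10.0), p, variant
        )
        v_only = predict_recognition(
            StimulusCondition("V", "divided", blur=10.0), p, variant
        )
        assert av_no_sound == pytest.approx(v_only, abs=1e-9)

        av_no_video = predict_recognition(
            StimulusCondition("AV", "divided", snr=0.0, blur=1e4), p, variant
        )
        lam_a = p.lapses.a_focused if variant == "trade-off" else p.lapses.a_divided
        aud_chain = apply_guess(apply_lapse(auditory_pf(0.0, p.auditory), lam_a))
        assert av_no_video == pytest.approx(aud_chain, abs=1e-9)


class TestMEI:
    def test_zero_for_equal_task_lapses(self):
        params = ParticipantParams(AUD, VIS, LapseSet.vis_shared(0.15, 0.15, 0.5))
        cond = StimulusCondition("AV", "divided", snr=0.0, blur=10.0)
        assert mei(cond, params) == pytest.approx(0.0, abs=1e-15)

    def test_ci_group_means_reproduce_printed_index(self, ci_group_params):
        cond = StimulusCondition("AV", "divided", snr=0.0, blur=20.0)
        assert mei(cond, ci_group_params) == pytest.approx(0.22, abs=0.005)

    def test_nh_group_means_stay_marginal(self, nh_group_params):
        """NH enhancement over moderate SNRs and the common blurs is small."""
        values = [
            mei(StimulusCondition("AV", "divided", snr=s, blur=b), nh_group_params)
            for s in (-10.0, -5.0, 0.0, 5.0, 10.0)
            for b in (0.0, 6.0, 12.0, 16.0, 20.0)
        ]
        assert min(values) >= 0.005
        assert max(values) <= 0.036

    @given(
        lam_foc=st.floats(0.0, 0.8),
        extra=st.floats(0.0, 0.19),
        snr=st.floats(-20, 20),
        blur=st.floats(0, 40),
    )
    def test_nonnegative_whenever_divided_lapse_dominates(self, lam_foc, extra, snr, blur):
        params = ParticipantParams(AUD, VIS, LapseSet.vis_shared(lam_foc, lam_foc + extra, 0.4))
        cond = StimulusCondition("AV", "divided", snr=snr, blur=blur)
        assert mei(cond, params) >= -1e-12

    def test_requires_audiovisual_condition(self, ci_group_params):
        with pytest.raises(InvalidParameterError):
            mei(StimulusCondition("V", "divided", blur=5.0), ci_group_params)
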