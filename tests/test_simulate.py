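"""Tests of the synthetic cohort and experiment generator."""

import io as _io

import numpy as np
import pandas as pd
import pytest

from avspeech import (
    AuditoryParams,
    DesignConfig,
    GroupHyperParams,
    LapseSet,
    ParamDist,
    ParticipantParams,
    VisualParams,
    build_design,
    draw_participants,
    individualize_levels,
    predict_recognition,
    simulate_cohort,
    simulate_responses,
)
from avspeech.io import SchemaError, read_trials, validate_trials, write_trials
from avspeech.psychometrics import InvalidParameterError, StimulusCondition
from avspeech.simulate import TRIAL_COLUMNS


class TestDrawParticipants:
    def test_deterministic_for_fixed_seed(self):
        hyper = GroupHyperParams.nh_defaults()
        a = draw_participants(hyper, 5, seed=42)
        b = draw_participants(hyper, 5, seed=42)
        assert a == b
        c = draw_participants(hyper, 5, seed=43)
        assert a != c

    def test_zero_scale_collapses_to_group_locations(self):
        hyper = GroupHyperParams(
            cohort="NH",
            theta_a=ParamDist(-12.0, 0.0),
            omega=ParamDist(7.4, 0.0, "log"),
            theta_v=ParamDist(18.3, 0.0, "log"),
            lam_a_focused=ParamDist(0.11, 0.0, "logit"),
            lam_a_divided=ParamDist(0.15, 0.0, "logit"),
            lam_v=ParamDist(0.54, 0.0, "logit"),
        )
        for p in draw_participants(hyper, 3, seed=0):
            assert p.auditory.threshold_db == pytest.approx(-12.0)
            assert p.auditory.width_db == pytest.approx(7.4)
            assert p.visual.threshold_px == pytest.approx(18.3)
            assert p.lapses.a_focused == pytest.approx(0.11)

    def test_draws_respect_parameter_supports(self):
        # constrained transforms keep widths/thresholds positive, lapses in [0,1]
        for p in draw_participants(GroupHyperParams.ci_defaults(), 50, seed=7):
            assert p.auditory.width_db > 0
            assert p.visual.threshold_px > 0
            assert 0 <= p.lapses.a_divided <= 1

    def test_negative_scale_rejected(self):
        with pytest.raises(InvalidParameterError):
            ParamDist(0.0, -1.0)


class TestIndividualizeLevels:
    PARAMS = ParticipantParams(
        AuditoryParams(-12.0, 7.4), VisualParams(18.3),
        LapseSet.vis_shared(0.0, 0.0, 0.0),
    )

    def test_midpoint_target_inverts_guess_transform(self):
        """0.9 F + 0.1 = 0.5 has the closed-form solution F = 4/9."""
        (snr,) = individualize_levels(self.PARAMS, [0.5], "A")
        f = 1 / (1 + np.exp(-(2 * np.log(9) / 7.4) * (snr - -12.0)))
        assert f == pytest.approx(4 / 9, abs=1e-10)
        cond = StimulusCondition("A", "focused", snr=float(snr))
        assert predict_recognition(cond, self.PARAMS) == pytest.approx(0.5, abs=1e-10)

    def test_floor_target_lands_far_below_threshold(self):
        with pytest.warns(UserWarning, match="clipped"):
            (snr,) = individualize_levels(self.PARAMS, [0.0], "A")
        cond = StimulusCondition("A", "focused", snr=float(snr))
        assert predict_recognition(cond, self.PARAMS) == pytest.approx(0.1, abs=1e-3)

    def test_visual_levels_reproduce_targets_forward(self):
        params = ParticipantParams(
            AuditoryParams(-12.0, 7.4), VisualParams(18.3),
            LapseSet.vis_shared(0.1, 0.1, 0.46),
        )
        targets = np.array([0.45, 0.35, 0.25, 0.15])
        blurs = individualize_levels(params, targets, "V")
        for target, blur in zip(targets, blurs):
            cond = StimulusCondition("V", "focused", blur=float(blur))
            assert predict_recognition(cond, params) == pytest.approx(target, abs=1e-9)

    def test_unreachable_target_clips_to_ceiling(self):
        params = ParticipantParams(
            AuditoryParams(-12.0, 7.4), VisualParams(18.3),
            LapseSet.vis_shared(0.0, 0.0, 0.5),  # visual ceiling 0.55
        )
        with pytest.warns(UserWarning, match="clipped"):
            (blur,) = individualize_levels(params, [0.9], "V")
        assert blur >= 0
        cond = StimulusCondition("V", "focused", blur=float(blur))
        assert predict_recognition(cond, params) <= 0.55


class TestBuildDesign:
    PARAMS = ParticipantParams(
        AuditoryParams(-3.0, 10.0), VisualParams(18.0),
        LapseSet.vis_shared(0.18, 0.4, 0.46),
    )

    def test_divided_grid_covers_25_balanced_combinations(self):
        design = build_design("divided", self.PARAMS, DesignConfig(n_divided_trials=100), seed=1)
        combos = design.trials.groupby(["snr_db", "blur_px"], dropna=False).size()
        assert len(combos) == 25
        assert (combos == 4).all()
        # unisensory rows: signal-absent column (V) and 70-px blur row (A)
        mods = design.trials["modality"]
        assert (mods[design.trials["snr_db"].isna()] == "V").all()
        assert set(mods) == {"A", "V", "AV"}

    def test_focused_auditory_block_has_no_informative_video(self):
        design = build_design("focused", self.PARAMS, seed=2)
        aud = design.trials[design.trials["modality"] == "A"]
        assert aud["blur_px"].isna().all()
        assert aud["snr_db"].nunique() == 8
        vis = design.trials[design.trials["modality"] == "V"]
        assert vis["snr_db"].isna().all()
        assert set(vis["blur_px"]) == {0.0, 6.0, 12.0, 16.0, 20.0}

    def test_sentences_are_never_repeated(self):
        design = build_design("divided", self.PARAMS, seed=3)
        assert design.trials["sentence_id"].is_unique

    def test_counts_outside_printed_ranges_rejected(self):
        with pytest.raises(InvalidParameterError):
            DesignConfig(n_divided_trials=50)
        with pytest.raises(InvalidParameterError):
            DesignConfig(n_focused_auditory=200)
        with pytest.raises(InvalidParameterError):
            DesignConfig(n_auditory_levels=2)


class TestSimulateResponses:
    def test_certain_recognition_yields_full_sentences(self):
        # zero lapse, zero blur video: post-guess probability is exactly 1
        params = ParticipantParams(
            AuditoryParams(-12.0, 7.4), VisualParams(18.0),
            LapseSet.vis_shared(0.0, 0.0, 0.0),
        )
        design = build_design("focused", params, seed=0)
        out = simulate_responses(design, params, seed=0)
        vis0 = out[(out["modality"] == "V") & (out["blur_px"] == 0.0)]
        assert (vis0["n_correct"] == 5).all()

    def test_empirical_rates_converge_to_model_probabilities(self):
        """Law of large numbers at 10,000 sentences on a fixed condition."""
        params = ParticipantParams(
            AuditoryParams(-3.0, 10.0), VisualParams(18.0),
            LapseSet.vis_shared(0.18, 0.4, 0.46),
        )
        trials = pd.DataFrame(
            {"sentence_id": np.arange(10_000), "modality": "AV",
             "snr_db": 0.0, "blur_px": 12.0}
        )
        from avspeech.simulate import ExperimentDesign

        design = ExperimentDesign(task="divided", trials=trials)
        out = simulate_responses(design, params, "trade-off", seed=5)
        p_model = predict_recognition(
            StimulusCondition("AV", "divided", snr=0.0, blur=12.0), params, "trade-off"
        )
        p_hat = out["n_correct"].sum() / out["n_words"].sum()
        assert p_hat == pytest.approx(p_model, abs=0.01)

    def test_identical_seeds_give_byte_identical_tables(self):
        hyper = GroupHyperParams.ci_defaults()
        a, _ = simulate_cohort(hyper, 2, seed=9)
        b, _ = simulate_cohort(hyper, 2, seed=9)
        buf_a, buf_b = _io.StringIO(), _io.StringIO()
        write_trials(a, buf_a)
        write_trials(b, buf_b)
        assert buf_a.getvalue() == buf_b.getvalue()
        c, _ = simulate_cohort(hyper, 2, seed=10)
        assert not a.equals(c)

    def test_saturation_matches_published_focused_levels(self):
        """NH-like cohort saturates near 90% correct at the easiest SNR."""
        hyper = GroupHyperParams.nh_defaults()
        cfg = DesignConfig(n_focused_auditory=60, n_focused_visual=40)
        trials, _ = simulate_cohort(hyper, 14, tasks=("focused",), config=cfg, seed=17)
        aud = trials[trials["modality"] == "A"].copy()
        top = aud.loc[aud.groupby("participant_id")["snr_db"].idxmax().values]
        tops = aud.merge(top[["participant_id", "snr_db"]], on=["participant_id", "snr_db"])
        rate = tops["n_correct"].sum() / tops["n_words"].sum()
        assert rate == pytest.approx(0.87, abs=0.05)


class TestTrialTableIO:
    def test_roundtrip_preserves_schema_and_values(self, tmp_path):
        trials, _ = simulate_cohort(GroupHyperParams.ci_defaults(), 2, seed=3)
        path = tmp_path / "trials.csv"
        write_trials(trials, path)
        back = read_trials(path)
        assert list(back.columns) == TRIAL_COLUMNS
        pd.testing.assert_frame_equal(
            back,
            trials[TRIAL_COLUMNS].reset_index(drop=True),
            check_exact=False,
            atol=1e-4,
        )

    def test_malformed_modality_reported_with_row_number(self):
        trials, _ = simulate_cohort(GroupHyperParams.ci_defaults(), 1, seed=3)
        bad = trials[TRIAL_COLUMNS].copy()
        bad.loc[2, "modality"] = "audio"
        with pytest.raises(SchemaError, match=r"invalid modality.*\[3\]"):
            validate_trials(bad)

    def test_trial_without_any_stimulus_rejected(self):
        trials, _ = simulate_cohort(GroupHyperParams.ci_defaults(), 1, seed=3)
        bad = trials[TRIAL_COLUMNS].copy()
        bad.loc[0, ["snr_db", "blur_px"]] = np.nan
        with pytest.raises(SchemaError, match="both stimulus dimensions absent"):
            validate_trials(bad)
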