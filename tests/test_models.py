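"""Inference battery: identifiability, breakpoint search, logistic, RT."""

import numpy as np
import pandas as pd
import pytest

from frogpan import (
    CohortSpec,
    RTParams,
    UpdateRuleParams,
    build_analysis_table,
    simulate_cohort,
)
from frogpan.models import (
    ConditionLearningRateModel,
    FitError,
    QuadraticUpdateModel,
    ReactionTimeModel,
    SegmentedUpdateModel,
    SeparationError,
    ThresholdLogisticModel,
)


class TestConditionModel:
    def test_zero_noise_recovers_composites(self, zero_linear_table):
        m = ConditionLearningRateModel().fit(zero_linear_table)
        assert m.composite_lr_["fluct_gradual"][0] == pytest.approx(0.528, abs=1e-6)
        assert m.coef_["abs_pe:abruptly_changed"] == pytest.approx(0.165, abs=1e-6)
        assert m.coef_["intercept"] == pytest.approx(1.017, abs=1e-6)
        assert m.composite_lr_["abruptly_changed"][0] == pytest.approx(0.693, abs=1e-6)

    def test_composite_is_slope_plus_interaction(self, noisy_table):
        m = ConditionLearningRateModel().fit(noisy_table)
        for lbl in ("gradually_changed", "fluct_abrupt", "abruptly_changed"):
            assert m.composite_lr_[lbl][0] == pytest.approx(
                m.coef_["abs_pe"] + m.coef_[f"abs_pe:{lbl}"]
            )

    def test_fip_ordering_on_default_cohort(self, noisy_table):
        m = ConditionLearningRateModel().fit(noisy_table)
        assert (
            m.composite_lr_["abruptly_changed"][0]
            > m.composite_lr_["fluct_gradual"][0]
        )

    def test_missing_level_raises(self, noisy_table):
        sub = noisy_table[noisy_table.condition != "abruptly_changed"]
        with pytest.raises(FitError, match="abruptly_changed"):
            ConditionLearningRateModel().fit(sub)

    def test_single_participant_raises(self, noisy_table):
        sub = noisy_table[noisy_table.participant_id == 1]
        with pytest.raises(FitError):
            ConditionLearningRateModel().fit(sub)

    def test_sklearn_params_round_trip(self):
        m = ConditionLearningRateModel(drop_nonupdating=False)
        assert m.get_params()["drop_nonupdating"] is False
        m.set_params(drop_nonupdating=True)
        assert m.get_params()["drop_nonupdating"] is True


class TestQuadraticModel:
    def test_exact_quadratic_recovery(self):
        # synthetic exact-quadratic responses: coefficients to 1e-8
        rng = np.random.default_rng(0)
        n = 600
        df = pd.DataFrame(
            {
                "participant_id": np.repeat(np.arange(6), 100),
                "abs_pe": rng.uniform(0, 12, n),
            }
        )
        df["dir_update"] = 0.7 + 0.3 * df.abs_pe + 0.05 * df.abs_pe**2
        df["update"] = df["dir_update"]
        df["is_nonupdating"] = False
        m = QuadraticUpdateModel().fit(df)
        assert m.coef_["intercept"] == pytest.approx(0.7, abs=1e-8)
        assert m.coef_["abs_pe"] == pytest.approx(0.3, abs=1e-8)
        assert m.coef_["abs_pe_sq"] == pytest.approx(0.05, abs=1e-8)

    def test_positive_curvature_under_segmented_truth(self, segmented_noisy_table):
        m = QuadraticUpdateModel().fit(segmented_noisy_table)
        assert m.coef_["abs_pe_sq"] > 0
        assert m.zvalues_["abs_pe_sq"] > 3


class TestSegmentedModel:
    def test_zero_noise_recovers_breakpoint(self, zero_segmented_table):
        m = SegmentedUpdateModel().fit(zero_segmented_table)
        assert m.psi_ == pytest.approx(5.337, abs=0.05)   # grid resolution
        assert m.delta_ == pytest.approx(0.536, abs=1e-4)  # after refinement
        assert m.beta0_ == pytest.approx(0.916, abs=1e-4)
        assert m.beta1_ == pytest.approx(0.536, abs=1e-4)

    def test_continuity_at_knot(self, zero_segmented_table):
        m = SegmentedUpdateModel().fit(zero_segmented_table)
        eps = 1e-7
        lo = m.predict(pd.DataFrame({"abs_pe": [m.psi_ - eps]}))
        hi = m.predict(pd.DataFrame({"abs_pe": [m.psi_ + eps]}))
        assert abs(hi - lo) < 1e-5

    def test_fixed_knot_equals_two_regressor_mixed_fit(self, segmented_noisy_table):
        # the profile at a fixed psi is exactly the LMM on [1, x, (x-psi)+]
        import statsmodels.api as sm

        m = SegmentedUpdateModel()
        sub = m._rows(segmented_noisy_table)
        x = sub.abs_pe.to_numpy()
        psi = 5.0
        res = m._fit_at(x, sub.dir_update.to_numpy(), sub.participant_id.to_numpy(), psi)
        X = np.column_stack([np.ones(len(x)), x, np.maximum(0, x - psi)])
        ref = sm.MixedLM(sub.dir_update.to_numpy(), X,
                         groups=sub.participant_id.to_numpy()).fit(reml=False)
        assert np.allclose(res.params, ref.fe_params, atol=1e-6)
        assert np.isclose(res.loglik, ref.llf, atol=1e-5)

    def test_profile_maximizer_matches_brute_force(self):
        # small instance: exhaustive fine grid vs grid+refinement
        rng = np.random.default_rng(42)
        n = 400
        x = rng.uniform(0, 12, n)
        g = np.repeat(np.arange(4), 100)
        y = (
            1.0 + 0.5 * x + 0.6 * np.maximum(0, x - 5.0)
            + rng.normal(0, 0.4, n)
            + np.array([0.3, -0.1, 0.2, -0.4])[g]
        )
        df = pd.DataFrame(
            {"participant_id": g, "abs_pe": x, "dir_update": y, "update": y,
             "is_nonupdating": False}
        )
        m = SegmentedUpdateModel(psi_step=0.05).fit(df)
        sub = m._rows(df)
        fine = np.arange(3.0, 7.0, 0.005)
        lls = [
            m._fit_at(x, y, g, p).loglik
            for p in fine
        ]
        brute = fine[int(np.argmax(lls))]
        assert abs(m.psi_ - brute) <= 0.01
        # and the profile stored for the same psi agrees to 1e-8
        row = m.profile_[np.isclose(m.profile_.psi, 5.0)]
        assert np.isclose(
            row.loglik.iloc[0], m._fit_at(x, y, g, 5.0).loglik, atol=1e-8
        )

    def test_single_slope_data_flags_flat_profile(self):
        rng = np.random.default_rng(1)
        n = 800
        x = rng.uniform(0, 12, n)
        g = np.repeat(np.arange(8), 100)
        y = 1.0 + 0.5 * x + rng.normal(0, 0.5, n)
        df = pd.DataFrame(
            {"participant_id": g, "abs_pe": x, "dir_update": y, "update": y,
             "is_nonupdating": False}
        )
        with pytest.warns(RuntimeWarning):
            m = SegmentedUpdateModel().fit(df)
        assert m.flat_profile_ or m.boundary_flag_
        assert abs(m.delta_) < 0.1
        lo, hi = m.psi_ci_
        assert (hi - lo) > 5 or np.isnan(lo)

    def test_psi_strictly_inside_grid(self, segmented_noisy_table):
        m = SegmentedUpdateModel().fit(segmented_noisy_table)
        assert 1.0 < m.psi_ < 12.0 and not m.boundary_flag_
        lo, hi = m.psi_ci_
        assert lo <= m.psi_ <= hi

    def test_no_points_above_any_candidate_raises(self):
        df = pd.DataFrame(
            {
                "participant_id": np.repeat([1, 2], 50),
                "abs_pe": np.full(100, 0.5),
                "dir_update": np.ones(100),
                "update": np.ones(100),
                "is_nonupdating": np.zeros(100, bool),
            }
        )
        with pytest.raises(FitError):
            SegmentedUpdateModel().fit(df)

    def test_bootstrap_ci_brackets_estimate(self, segmented_noisy_table):
        m = SegmentedUpdateModel(
            ci_method="bootstrap", n_boot=20, random_state=0
        ).fit(segmented_noisy_table)
        lo, hi = m.psi_ci_
        assert lo < hi and 1.0 <= lo and hi <= 12.0


class TestThresholdLogistic:
    def test_intercept_is_logit_of_baseline_rate(self, noisy_table):
        m = ThresholdLogisticModel(threshold=5.337).fit(noisy_table)
        p = m.cell_rates_["fluct_gradual"]
        assert m.coef_["intercept"] == pytest.approx(np.log(p / (1 - p)), abs=1e-6)

    def test_abrupt_odds_dominate(self, noisy_table):
        m = ThresholdLogisticModel(threshold=5.337).fit(noisy_table)
        assert m.coef_["abruptly_changed"] > 0
        assert m.odds_ratio_["abruptly_changed"] > 100
        assert m.odds_ratio_["abruptly_changed"] == m.odds_ratio_.max()

    def test_constant_outcome_raises(self, noisy_table):
        with pytest.raises(SeparationError):
            ThresholdLogisticModel(threshold=1e6).fit(noisy_table)

    def test_pure_cell_sets_separation_flag(self):
        rng = np.random.default_rng(0)
        n = 400
        conds = np.tile(
            ["fluct_gradual", "gradually_changed", "fluct_abrupt", "abruptly_changed"],
            n // 4,
        )
        abs_pe = rng.uniform(0, 4, n)
        abs_pe[conds == "abruptly_changed"] = 10.0  # pure cell above threshold
        df = pd.DataFrame(
            {
                "participant_id": np.repeat(np.arange(8), n // 8),
                "condition": conds,
                "abs_pe": abs_pe,
                "rt": np.full(n, 0.8),
                "pe": abs_pe,
                "update": abs_pe,
            }
        )
        m = ThresholdLogisticModel(threshold=5.0).fit(df)
        assert m.separation_flag_


class TestReactionTimeModel:
    def test_zero_noise_offsets_match_condition_means(self, zero_linear_table):
        m = ReactionTimeModel().fit(zero_linear_table)
        assert m.intercept_ == pytest.approx(0.883, abs=1e-6)
        assert m.offsets_["abruptly_changed"] == pytest.approx(0.222, abs=1e-6)
        assert m.offsets_["gradually_changed"] == pytest.approx(-0.033, abs=1e-6)
        assert m.offsets_["fluct_abrupt"] == pytest.approx(-0.028, abs=1e-6)

    def test_excluded_rts_do_not_enter_fit(self, noisy_table):
        m = ReactionTimeModel().fit(noisy_table)
        assert m.n_obs_ == int(noisy_table.rt_included.sum())

    def test_shuffled_labels_null_offsets(self, noisy_table):
        rng = np.random.default_rng(0)
        shuffled = noisy_table.copy()
        perm = shuffled.condition.to_numpy().copy()
        rng.shuffle(perm)
        shuffled["condition"] = perm
        from frogpan.metrics import code_conditions

        shuffled = code_conditions(shuffled.drop(
            columns=[c for c in shuffled.columns if c.startswith("d_")]
        ))
        m = ReactionTimeModel().fit(shuffled)
        for off in m.offsets_.values():
            assert abs(off) < 0.02  # permutation null

    def test_abrupt_offset_positive_on_default_cohort(self, noisy_table):
        m = ReactionTimeModel().fit(noisy_table)
        assert m.offsets_["abruptly_changed"] > 0
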