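import numpy as np
import pandas as pd
import pytest

from microtrait.synth import CohortSimConfig, simulate_trait_table, trait_analysis_table
from microtrait.traitstats import (
    AQ_SUBSCALES,
    TraitModerationModel,
    compare_fixed_vs_random_intercept,
    icc_oneway,
    moderation_model1,
    regress_standardized,
    run_full_analysis,
    score_aq,
    to_long_table,
)


class TestScoreAq:
    def test_scale_floor_and_ceiling(self):
        lo = score_aq([1] * 12)
        hi = score_aq([6] * 12)
        assert lo.total == 1.0 and lo.physical == lo.verbal == lo.hostility == lo.anger == 1.0
        assert hi.total == 6.0

    def test_block_scoring_hand_example(self):
        scores = score_aq([2, 2, 2, 3, 3, 3, 4, 4, 4, 5, 5, 5])
        assert (scores.physical, scores.verbal, scores.hostility, scores.anger) == (
            2.0, 3.0, 4.0, 5.0,
        )
        assert scores.total == 3.5

    @pytest.mark.parametrize(
        "items",
        [
            [1] * 11,                      # wrong length
            [1] * 11 + [7],                # out of range
            [1] * 11 + [0],
            [1] * 11 + [float("nan")],     # missing
        ],
    )
    def test_invalid_items_raise(self, items):
        with pytest.raises(ValueError):
            score_aq(items)

    def test_subscale_map_covers_all_items_once(self):
        indices = sorted(i for ix in AQ_SUBSCALES.values() for i in ix)
        assert indices == list(range(12))


def _long_table(rng, n_subjects, sd_between, sd_within, mean=80.0):
    subj = rng.normal(mean, sd_between, n_subjects)
    rows = []
    for i, mu in enumerate(subj):
        for t in "ABCD":
            rows.append(
                {
                    "subject_id": f"s{i}",
                    "microstate_type": t,
                    "duration_ms": mu + rng.normal(0, sd_within),
                    "occurrence_hz": 250.0 / max(mu + rng.normal(0, sd_within), 1.0),
                }
            )
    return pd.DataFrame(rows)


class TestIcc:
    def test_zero_within_variance_gives_one(self):
        df = _long_table(np.random.default_rng(0), 30, sd_between=10.0, sd_within=1e-12)
        assert icc_oneway(df).icc == pytest.approx(1.0, abs=1e-6)

    def test_zero_between_variance_gives_zero(self):
        rng = np.random.default_rng(1)
        df = _long_table(rng, 60, sd_between=1e-12, sd_within=5.0)
        assert icc_oneway(df).icc == pytest.approx(0.0, abs=0.05)

    def test_monte_carlo_recovery_of_planted_components(self):
        # sigma2_between = 3, sigma2_within = 1 -> ICC 0.75
        df = _long_table(
            np.random.default_rng(2), 100, sd_between=np.sqrt(3.0), sd_within=1.0
        )
        res = icc_oneway(df)
        assert 0.65 <= res.icc <= 0.85
        assert res.icc == pytest.approx(
            res.variance_between / (res.variance_between + res.variance_within)
        )

    def test_affine_invariance(self):
        rng = np.random.default_rng(3)
        df = _long_table(rng, 40, sd_between=8.0, sd_within=4.0)
        base = icc_oneway(df).icc
        for a, b in [(3.0, -100.0), (0.01, 5.0), (250.0, 0.0)]:
            scaled = df.copy()
            scaled["duration_ms"] = a * scaled["duration_ms"] + b
            assert icc_oneway(scaled).icc == pytest.approx(base, abs=1e-4)

    def test_degenerate_input_raises(self):
        df = _long_table(np.random.default_rng(0), 5, sd_between=1.0, sd_within=1.0)
        df["duration_ms"] = 80.0
        with pytest.raises(ValueError):
            icc_oneway(df)


class TestModelComparison:
    def test_strong_subject_intercepts_detected(self):
        # subject intercept SD = 3 x residual SD
        df = _long_table(np.random.default_rng(4), 100, sd_between=3.0, sd_within=1.0)
        res = compare_fixed_vs_random_intercept(df)
        assert res.p_value < 0.001
        assert res.lrt_statistic > 0

    def test_mixed_loglik_dominates_fixed(self):
        for seed in range(5):
            df = _long_table(np.random.default_rng(seed), 25, sd_between=2.0, sd_within=2.0)
            res = compare_fixed_vs_random_intercept(df)
            assert res.loglik_mixed >= res.loglik_fixed
            assert res.lrt_statistic >= 0

    def test_deterministic(self):
        df = _long_table(np.random.default_rng(6), 40, sd_between=2.0, sd_within=1.0)
        a = compare_fixed_vs_random_intercept(df)
        b = compare_fixed_vs_random_intercept(df)
        assert a == b

    def test_null_rejection_rate_is_conservative(self):
        """Boundary chi2(1) reference keeps size at or below the nominal 5%."""
        rng = np.random.default_rng(7)
        rejections = 0
        n_rep = 300
        for _ in range(n_rep):
            df = _long_table(rng, 25, sd_between=1e-9, sd_within=2.0)
            if compare_fixed_vs_random_intercept(df).p_value < 0.05:
                rejections += 1
        assert rejections / n_rep <= 0.06


class TestStandardizedRegression:
    def test_perfect_association(self):
        x = np.arange(20.0)
        res = regress_standardized(x, x)
        assert res.beta_standardized == pytest.approx(1.0)
        assert res.r_squared == pytest.approx(1.0)

    def test_beta_equals_pearson_and_r2_equals_beta2(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            x = rng.normal(size=50)
            y = 0.4 * x + rng.normal(size=50)
            res = regress_standardized(y, x)
            assert res.beta_standardized == pytest.approx(np.corrcoef(y, x)[0, 1], abs=1e-12)
            assert res.r_squared == pytest.approx(res.beta_standardized**2, abs=1e-9)
            assert abs(res.beta_standardized) <= 1.0

    def test_null_slope_near_zero_at_large_n(self):
        rng = np.random.default_rng(9)
        res = regress_standardized(rng.normal(size=10_000), rng.normal(size=10_000))
        assert abs(res.beta_standardized) < 0.03

    def test_constant_input_raises(self):
        with pytest.raises(ValueError):
            regress_standardized(np.ones(10), np.arange(10.0))


class TestModeration:
    def test_equal_slopes_give_zero_interaction(self):
        x = np.tile(np.linspace(-2, 2, 30), 2)
        g = np.array(["m"] * 30 + ["f"] * 30)
        y = 0.5 * x  # identical association in both groups, noiseless
        res = moderation_model1(y, x, g)
        assert res.interaction_b == pytest.approx(0.0, abs=1e-9)
        assert res.r_squared_change == pytest.approx(0.0, abs=1e-9)

    def test_coding_swap_flips_interaction_sign(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=120)
        g = np.array(["a"] * 60 + ["b"] * 60)
        y = np.where(g == "b", -0.5, 0.2) * x + 0.3 * rng.normal(size=120)
        res = moderation_model1(y, x, g)
        swapped = moderation_model1(y, x, np.where(g == "a", "z", "a"))
        assert swapped.interaction_b == pytest.approx(-res.interaction_b)
        assert swapped.p_value == pytest.approx(res.p_value)
        assert swapped.simple_slopes["a"].beta_standardized == pytest.approx(
            res.simple_slopes["b"].beta_standardized
        )

    def test_ci_brackets_estimate_and_df(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=101)
        g = np.array(["male"] * 43 + ["female"] * 58)
        y = rng.normal(size=101)
        res = moderation_model1(y, x, g)
        assert res.ci_low <= res.interaction_b <= res.ci_high
        assert res.df == 97
        assert res.n == 101

    def test_single_gender_raises(self):
        with pytest.raises(ValueError):
            moderation_model1(np.arange(10.0), np.arange(10.0), np.array(["m"] * 10))


class TestFullAnalysis:
    def _table(self, seed=12, n=101):
        cfg = CohortSimConfig(seed=seed, n_subjects=n)
        tab, _ = simulate_trait_table(cfg)
        return trait_analysis_table(tab)

    def test_grid_shape_and_determinism(self):
        at = self._table()
        a = run_full_analysis(at)
        b = run_full_analysis(at)
        assert len(a.grid) == 10  # 5 outcomes x 2 predictors
        pd.testing.assert_frame_equal(a.grid, b.grid)
        assert set(a.icc) == {"duration", "occurrence"}
        assert a.model_comparison["duration"].p_value < 0.001

    def test_planted_sign_pattern_appears_in_grid(self):
        at = self._table(seed=13, n=400)
        bundle = run_full_analysis(at, include_consistency=False)
        dur = bundle.grid[bundle.grid["predictor"] == "mean_duration_ms"]
        occ = bundle.grid[bundle.grid["predictor"] == "mean_occurrence_hz"]
        total_dur = dur[dur["outcome"] == "aq_total"].iloc[0]
        total_occ = occ[occ["outcome"] == "aq_total"].iloc[0]
        assert total_dur["beta_pooled"] < 0 < total_occ["beta_pooled"]
        assert total_dur["beta_male"] < total_dur["beta_female"]

    def test_null_cohorts_keep_nominal_false_positive_rate(self):
        rng = np.random.default_rng(14)
        pvals = []
        for _ in range(40):
            cfg = CohortSimConfig(
                seed=int(rng.integers(2**31)), n_subjects=101,
                beta_male=0.0, beta_female=0.0,
            )
            tab, _ = simulate_trait_table(cfg)
            bundle = run_full_analysis(trait_analysis_table(tab), include_consistency=False)
            pvals.extend(bundle.grid["p_pooled"])
            pvals.extend(bundle.grid["interaction_p"])
        rate = np.mean(np.asarray(pvals) < 0.05)
        assert 0.02 <= rate <= 0.09

    def test_missing_columns_fail_loudly(self):
        with pytest.raises(ValueError, match="columns"):
            run_full_analysis(pd.DataFrame({"gender": ["m", "f"]}))

    def test_model_object_round_trip(self):
        at = self._table(seed=15)
        res = TraitModerationModel.from_dataframe(at).fit()
        direct = moderation_model1(
            at["aq_total"].to_numpy(),
            at["mean_duration_ms"].to_numpy(),
            at["gender"].to_numpy(),
        )
        assert res.moderation.interaction_b == pytest.approx(direct.interaction_b)
        assert "interaction" in res.summary()

    def test_long_table_has_four_rows_per_subject(self):
        at = self._table(seed=16, n=10)
        long = to_long_table(at)
        assert len(long) == 40
        assert long.groupby("subject_id").size().eq(4).all()
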