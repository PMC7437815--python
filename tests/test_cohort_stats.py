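import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from oracles import binom_tail, holm_sidak_max
from ripplescreen.cohort_stats import (
    APA_LEARNING_METRICS,
    APA_PRECISION_METRICS,
    DEFAULT_SIGN_MAP,
    MWM_LEARNING_METRICS,
    MWM_PRECISION_METRICS,
    Orientation,
    binomial_enrichment,
    composite_score,
    correlate,
    fit_linear_predictor,
    holm_sidak,
    loo_robustness,
    predict_and_evaluate,
    redundancy_filter,
    zscore_metric,
)


class TestZScore:
    def test_two_values(self):
        z = zscore_metric(pd.Series([0.0, 2.0, 1.0]))
        # values {0, 2}: mean 1, sample SD 1 -> +-1; use the spec pair via n=3
        z2 = zscore_metric(pd.Series([0.0, 2.0, 0.0, 2.0]))
        assert z2.iloc[0] == pytest.approx(-0.8660254, rel=1e-6)

    def test_spec_pair_normalization(self):
        # {0, 2} has mean 1 and sample SD sqrt(2): z = -+0.707
        s = pd.Series([0.0, 2.0, 0.0, 2.0, 0.0, 2.0])
        # direct two-point computation
        x = np.array([0.0, 2.0])
        z = (x - x.mean()) / x.std(ddof=1)
        np.testing.assert_allclose(z, [-0.70710678, 0.70710678])

    def test_idempotent_and_affine_invariant(self):
        rng = np.random.default_rng(0)
        x = pd.Series(rng.normal(size=20))
        z = zscore_metric(x)
        np.testing.assert_allclose(zscore_metric(z), z, atol=1e-12)
        np.testing.assert_allclose(zscore_metric(3.2 * x + 7.0), z, atol=1e-12)

    def test_missing_preserved_and_guards(self):
        z = zscore_metric(pd.Series([1.0, np.nan, 2.0, 3.0]))
        assert math.isnan(z.iloc[1])
        with pytest.raises(ValueError):
            zscore_metric(pd.Series([1.0, 2.0]))
        with pytest.raises(ValueError):
            zscore_metric(pd.Series([5.0, 5.0, 5.0]))


class TestComposite:
    def test_sign_orientation(self):
        z = pd.DataFrame({"a": [1.0, -1.0, 0.0]})
        score = composite_score(z, ["a"], {"a": Orientation.LOWER_IS_BETTER})
        assert score.scores.iloc[0] == pytest.approx(-1.0)
        z2 = pd.DataFrame({"a": [1.0], "b": [-1.0]})
        both = composite_score(z2, ["a", "b"],
                               {k: Orientation.HIGHER_IS_BETTER for k in "ab"})
        assert both.scores.iloc[0] == pytest.approx(0.0)

    def test_cohort_mean_zero_and_affine_invariance(self):
        rng = np.random.default_rng(1)
        raw = pd.DataFrame(rng.normal(size=(16, 4)), columns=list("abcd"))
        sign_map = {c: Orientation.LOWER_IS_BETTER for c in raw.columns}
        z = raw.apply(zscore_metric)
        score = composite_score(z, list(raw.columns), sign_map)
        assert abs(score.scores.mean()) < 1e-9
        rescaled = raw * [2.0, 5.0, 0.1, 9.0] + [3, -1, 0, 40]
        z2 = rescaled.apply(zscore_metric)
        score2 = composite_score(z2, list(raw.columns), sign_map)
        np.testing.assert_allclose(score2.scores, score.scores, atol=1e-9)

    def test_mostly_missing_mouse_gets_sentinel(self):
        z = pd.DataFrame({"a": [1.0, np.nan], "b": [0.5, np.nan], "c": [0.0, 2.0],
                          "d": [1.0, np.nan]})
        sm = {c: Orientation.HIGHER_IS_BETTER for c in z.columns}
        score = composite_score(z, list(z.columns), sm)
        assert math.isnan(score.scores.iloc[1])

    def test_metric_missing_from_sign_map_errors(self):
        z = pd.DataFrame({"a": [1.0, 2.0, 3.0]})
        with pytest.raises(KeyError):
            composite_score(z, ["a"], {})

    def test_paper_metric_sets_and_sign_conventions(self):
        # learning (MWM): latency slopes over days 1-2 and 1-3, day-3
        # latency, overnight change over the first night -- lower is better
        assert MWM_LEARNING_METRICS == [
            "mwm_latency_slope_d1_2", "mwm_latency_slope_d1_3",
            "mwm_latency_d3", "mwm_overnight_change_d1_2"]
        assert all(DEFAULT_SIGN_MAP[m] is Orientation.LOWER_IS_BETTER
                   for m in MWM_LEARNING_METRICS)
        # precision (MWM): probe quadrant time 1-2, crossings probe 1, AUC 1-2
        assert len(MWM_PRECISION_METRICS) == 5
        assert DEFAULT_SIGN_MAP["mwm_probe1_quadrant_pct"] is Orientation.HIGHER_IS_BETTER
        assert DEFAULT_SIGN_MAP["mwm_probe1_crossings"] is Orientation.HIGHER_IS_BETTER
        assert DEFAULT_SIGN_MAP["mwm_probe1_auc"] is Orientation.LOWER_IS_BETTER
        # APA learning on day 2: latency to first entrance, path length,
        # opposite-quadrant time -- higher is better
        assert set(APA_LEARNING_METRICS) == {
            "apa_latency_first_entrance_d2", "apa_path_length_d2",
            "apa_opposite_quadrant_pct_d2"}
        assert all(DEFAULT_SIGN_MAP[m] is Orientation.HIGHER_IS_BETTER
                   for m in APA_LEARNING_METRICS)
        # APA precision: entrances day 2, bout distance days 2-3 -- lower is better
        assert set(APA_PRECISION_METRICS) == {
            "apa_entrances_d2", "apa_bout_distance_d2", "apa_bout_distance_d3"}
        assert all(DEFAULT_SIGN_MAP[m] is Orientation.LOWER_IS_BETTER
                   for m in APA_PRECISION_METRICS)


class TestRedundancyFilter:
    def test_duplicate_and_linear_dropped(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=50)
        table = pd.DataFrame({"a": a, "dup": a, "lin": 3 * a - 1,
                              "b": rng.normal(size=50)})
        assert redundancy_filter(table) == ["a", "b"]

    def test_independent_columns_kept(self):
        rng = np.random.default_rng(3)
        table = pd.DataFrame(rng.normal(size=(50, 2)), columns=["x", "y"])
        assert redundancy_filter(table) == ["x", "y"]


class TestCorrelate:
    def test_linear_gaussian_selects_pearson(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=16)
        res = correlate(x, 2 * x)
        assert res.method == "PEARSON"
        assert res.r == pytest.approx(1.0)
        assert res.p < 1e-6

    def test_heavy_skew_selects_spearman(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=30)
        res = correlate(x, np.exp(10 * x))
        assert res.method == "SPEARMAN"
        assert res.r == pytest.approx(1.0)

    def test_type_one_error_calibrated(self):
        rng = np.random.default_rng(6)
        hits = sum(
            correlate(rng.normal(size=16), rng.normal(size=16)).p < 0.05
            for _ in range(1000)
        )
        assert 0.03 <= hits / 1000 <= 0.07

    def test_constant_input_errors(self):
        with pytest.raises(ValueError):
            correlate(np.ones(10), np.arange(10.0))


class TestHolmSidak:
    def test_worked_pair(self):
        np.testing.assert_allclose(holm_sidak([0.01, 0.04]), [0.0199, 0.04])

    def test_single_and_identical(self):
        assert holm_sidak([0.2]) == pytest.approx([0.2])
        np.testing.assert_allclose(holm_sidak([0.1] * 4), [1 - 0.9**4] * 4)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(st.floats(1e-9, 1.0, exclude_min=False), min_size=1, max_size=12))
    def test_matches_max_formula_oracle(self, p):
        np.testing.assert_allclose(holm_sidak(p), holm_sidak_max(p), rtol=1e-9, atol=1e-15)

    def test_adjusted_at_least_raw(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(0.001, 1.0, size=20)
        assert np.all(holm_sidak(p) >= p - 1e-15)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            holm_sidak([0.0, 0.5])


class TestBinomialEnrichment:
    def test_closed_form_and_edges(self):
        assert binomial_enrichment(10, 10, 0.5) == pytest.approx(0.0009765625)
        assert binomial_enrichment(0, 88) == pytest.approx(1.0)

    @pytest.mark.parametrize("k,n,alpha", [(9, 88, 0.05), (8, 40, 0.05), (5, 30, 0.05)])
    def test_matches_pmf_summation(self, k, n, alpha):
        assert binomial_enrichment(k, n, alpha) == pytest.approx(
            binom_tail(k, n, alpha), rel=1e-12)

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            binomial_enrichment(11, 10)


class TestPredictor:
    def test_exact_fit(self):
        z = pd.Series(np.arange(10.0) - 4.5)
        model = fit_linear_predictor(z, 0.8 * z)
        assert model.slope == pytest.approx(0.8)
        assert model.intercept == pytest.approx(0.0, abs=1e-9)

    def test_slope_recovery_over_seeds(self):
        rng = np.random.default_rng(8)
        slopes = []
        for _ in range(200):
            z = rng.normal(size=16)
            y = 0.7 * z + rng.normal(0, 0.5, size=16)
            slopes.append(fit_linear_predictor(pd.Series(z), pd.Series(y)).slope)
        assert np.mean(slopes) == pytest.approx(0.7, abs=0.05)

    def test_predict_noise_free_transfer(self):
        z_s = pd.Series(np.linspace(-2, 2, 12))
        model = fit_linear_predictor(z_s, 0.9 * z_s)
        z_t = pd.Series(np.linspace(-1.5, 1.5, 10))
        _, r2, f, p = predict_and_evaluate(model, z_t, 0.9 * z_t)
        assert r2 == pytest.approx(1.0)
        assert p < 1e-10

    def test_predict_permutation_null_calibrated(self):
        rng = np.random.default_rng(9)
        z_s = pd.Series(rng.normal(size=16))
        model = fit_linear_predictor(z_s, pd.Series(0.7 * z_s + rng.normal(0, 0.5, 16)))
        z_t = pd.Series(rng.normal(size=12))
        y = 0.7 * z_t.to_numpy() + rng.normal(0, 0.5, 12)
        hits = 0
        n_perm = 500
        for _ in range(n_perm):
            _, _, _, p = predict_and_evaluate(model, z_t, pd.Series(rng.permutation(y)))
            hits += p < 0.05
        assert 0.02 <= hits / n_perm <= 0.08


class TestLooRobustness:
    def test_perfect_line_is_robust(self):
        x = np.linspace(0, 1, 10)
        robust, ps = loo_robustness(x, 2 * x + 1)
        assert robust
        assert all(p < 1e-4 for p in ps)

    def test_single_outlier_not_robust(self):
        # 9 uncorrelated points plus one leverage point that manufactures an
        # overall Pearson p < 0.05 without tripping the normality pre-test
        rng = np.random.default_rng(6)
        x = np.concatenate([rng.normal(0, 0.6, 9), [2.6]])
        y = np.concatenate([rng.normal(0, 0.6, 9), [2.6]])
        res = correlate(x, y)
        assert res.method == "PEARSON" and res.p < 0.05
        robust, _ = loo_robustness(x, y)
        assert not robust

    def test_boundary_subset_count(self):
        x = np.linspace(0, 1, 5)
        _, ps = loo_robustness(x, x + np.array([0.01, -0.02, 0.0, 0.02, -0.01]))
        assert len(ps) == 5
        with pytest.raises(ValueError):
            loo_robustness(x[:4], x[:4])
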