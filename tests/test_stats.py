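import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import gaitpheno as gp
from gaitpheno.stats import (
    HealthyReference,
    bca_interval,
    binarize_gmfcs,
    fit_clinical_vs_pattern,
    fit_pattern_lmm,
    group_contrast_bca,
    mm_regression,
    robust_age_regression,
    zscore_matrix,
)


class TestZscores:
    def test_mean_maps_to_zero_and_two_sd_to_two(self):
        ref = HealthyReference(mean=pd.Series({"a": 10.0}), sd=pd.Series({"a": 2.0}))
        z = zscore_matrix(pd.DataFrame({"a": [10.0, 14.0]}), ref)
        assert z["a"].tolist() == pytest.approx([0.0, 2.0])

    def test_self_standardization(self):
        rng = np.random.default_rng(0)
        frame = pd.DataFrame(rng.normal(5, 3, size=(200, 4)), columns=list("abcd"))
        z = zscore_matrix(frame, HealthyReference.from_matrix(frame))
        assert np.allclose(z.mean(), 0.0, atol=1e-12)
        assert np.allclose(z.std(ddof=1), 1.0, atol=1e-12)

    def test_zero_sd_rejected(self):
        ref = HealthyReference(mean=pd.Series({"a": 1.0}), sd=pd.Series({"a": 0.0}))
        with pytest.raises(ValueError, match="a"):
            zscore_matrix(pd.DataFrame({"a": [1.0]}), ref)


def _simulate_lmm(rng, n_subjects=20, cycles_per_subject=8, effect=0.0):
    """Cycle-level response with subject random intercepts and an optional
    pattern fixed effect (patterns drawn per cycle)."""
    rows = []
    for s in range(n_subjects):
        intercept = rng.normal(0, 1.0)
        for c in range(cycles_per_subject):
            pattern = rng.integers(0, 4)
            rows.append({
                "subject": f"s{s}",
                "pattern": str(pattern),
                "y": 10.0 + intercept + effect * (pattern == 0) + rng.normal(0, 1.0),
            })
    return pd.DataFrame(rows)


class TestMixedModels:
    def test_large_planted_effect_detected(self):
        rng = np.random.default_rng(1)
        frame = _simulate_lmm(rng, effect=2.0, n_subjects=26)
        res = fit_pattern_lmm(frame["y"], frame["pattern"], frame["subject"])
        assert res.df == 3
        assert res.p_value < 1e-6

    def test_power_above_95pct_for_two_sd_effect(self):
        rng = np.random.default_rng(2)
        rejections = 0
        n_rep = 40
        for _ in range(n_rep):
            frame = _simulate_lmm(rng, effect=2.0, n_subjects=25)
            res = fit_pattern_lmm(frame["y"], frame["pattern"], frame["subject"])
            rejections += res.p_value < 0.05
        assert rejections / n_rep > 0.95

    def test_lrt_invariant_to_affine_response_rescaling(self):
        rng = np.random.default_rng(3)
        frame = _simulate_lmm(rng, effect=0.8)
        r1 = fit_pattern_lmm(frame["y"], frame["pattern"], frame["subject"])
        r2 = fit_pattern_lmm(3.0 * frame["y"] - 7.0, frame["pattern"], frame["subject"])
        assert r2.lrt_statistic == pytest.approx(r1.lrt_statistic, abs=1e-4)

    def test_degenerate_inputs_rejected(self):
        frame = _simulate_lmm(np.random.default_rng(4))
        with pytest.raises(ValueError):
            fit_pattern_lmm(frame["y"], pd.Series(["1"] * len(frame)), frame["subject"])


class TestClinicalVsPattern:
    def test_two_pattern_odds_ratio_matches_cross_product(self):
        # pattern A: 8 yes / 2 no; pattern B: 2 yes / 8 no -> OR(B vs A) = 1/16
        y = pd.Series([1] * 8 + [0] * 2 + [1] * 2 + [0] * 8, dtype=float)
        patterns = pd.Series(["A"] * 10 + ["B"] * 10)
        res = fit_clinical_vs_pattern(y, patterns, kind="binary", reference="A")
        assert res.iloc[0]["estimate"] == pytest.approx(1.0 / 16.0, rel=1e-4)
        # and symmetrically OR(A vs B) = 16
        res2 = fit_clinical_vs_pattern(y, patterns, kind="binary", reference="B")
        assert res2.iloc[0]["estimate"] == pytest.approx(16.0, rel=1e-4)

    def test_independent_binary_feature_or_near_one(self):
        rng = np.random.default_rng(5)
        y = pd.Series(rng.integers(0, 2, 400).astype(float))
        patterns = pd.Series(rng.choice(["1", "2", "3"], 400))
        res = fit_clinical_vs_pattern(y, patterns, kind="binary")
        assert np.allclose(res["estimate"], 1.0, atol=0.6)
        assert (res["p_value"] > 0.01).all()

    def test_reference_defaults_to_most_common_pattern(self):
        y = pd.Series([1.0, 0.0, 1.0, 0.0, 1.0, 1.0])
        patterns = pd.Series(["2", "2", "2", "2", "1", "1"])
        res = fit_clinical_vs_pattern(y, patterns, kind="binary")
        assert (res["reference"] == "2").all()

    def test_separation_flagged_not_fatal(self):
        y = pd.Series([1.0] * 10 + [0.0] * 5 + [1.0] * 5)
        patterns = pd.Series(["A"] * 10 + ["B"] * 10)   # A all-yes: separated
        res = fit_clinical_vs_pattern(y, patterns, kind="binary", reference="A")
        assert res.iloc[0]["infinite_or"]

    def test_quantitative_feature_linear_model(self):
        rng = np.random.default_rng(6)
        patterns = pd.Series(rng.choice(["1", "2"], 300))
        age = pd.Series(8.0 + 3.0 * (patterns == "2") + rng.normal(0, 1, 300))
        res = fit_clinical_vs_pattern(age, patterns, kind="quantitative", reference="1")
        assert res.iloc[0]["estimate"] == pytest.approx(3.0, abs=0.4)
        assert res.iloc[0]["anova_p"] < 1e-10

    def test_gmfcs_binarization(self):
        s = pd.Series(["I", "II", "III", "I"])
        assert binarize_gmfcs(s).tolist() == [0.0, 1.0, 1.0, 0.0]


class TestRobustRegression:
    def test_noiseless_line_recovered_exactly(self):
        age = np.linspace(4, 17, 60)
        y = 2.0 - 0.05 * age
        X = np.column_stack([np.ones_like(age), age])
        fit = mm_regression(X, y, names=["intercept", "age"], seed=0)
        assert fit.coef[1] == pytest.approx(-0.05, abs=1e-8)

    def test_matches_ols_on_clean_gaussian_data(self):
        rng = np.random.default_rng(7)
        x = rng.uniform(0, 10, 300)
        y = 1.0 + 0.7 * x + rng.normal(0, 0.5, 300)
        X = np.column_stack([np.ones_like(x), x])
        fit = mm_regression(X, y, seed=1)
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        # both estimators are consistent here; they agree to ~1 standard error
        assert np.all(np.abs(fit.coef - ols) < 1.5 * fit.se)

    def test_resists_gross_contamination_where_ols_fails(self):
        rng = np.random.default_rng(8)
        n = 300
        age = rng.uniform(4, 17, n)
        y = 2.0 - 0.05 * age + rng.normal(0, 0.05, n)
        # 10% gross outliers placed at high leverage to bias the LS slope
        bad = rng.choice(n, size=n // 10, replace=False)
        y[bad] = 50.0
        age[bad] = rng.uniform(15, 17, len(bad))
        X = np.column_stack([np.ones_like(age), age])
        ols_slope = np.linalg.lstsq(X, y, rcond=None)[0][1]
        fit = mm_regression(X, y, seed=2)
        assert abs(ols_slope - (-0.05)) > 0.02
        assert fit.coef[1] == pytest.approx(-0.05, abs=0.005)

    def test_age_condition_interaction_model(self):
        rng = np.random.default_rng(9)
        n = 400
        age = rng.uniform(4, 17, n)
        cond = rng.integers(0, 2, n).astype(float)
        y = 1.3 - 0.05 * age - 0.1 * cond - 0.03 * age * cond + rng.normal(0, 0.2, n)
        fit = robust_age_regression(
            pd.Series(y), pd.Series(age),
            pd.Series(np.where(cond == 1, "HSP", "healthy")), seed=3)
        frame = fit.to_frame().set_index("term")
        # age and age x condition are collinear, so recovery is asserted on
        # the estimator's own standard-error scale
        for term, truth in (("age", -0.05), ("condition", -0.1), ("age:condition", -0.03)):
            z = abs(frame.loc[term, "estimate"] - truth) / frame.loc[term, "se"]
            assert z < 3.5, f"{term}: {frame.loc[term, 'estimate']} vs {truth}"

    def test_too_few_observations_per_condition_rejected(self):
        with pytest.raises(ValueError):
            robust_age_regression(pd.Series(np.zeros(12)), pd.Series(np.arange(12.0)),
                                  pd.Series(["HSP"] * 11 + ["healthy"]))


class TestBcaContrasts:
    def test_identical_groups_ci_contains_zero(self):
        rng = np.random.default_rng(10)
        v = rng.normal(0, 1, 200)
        res = group_contrast_bca(pd.Series(np.r_[v, v]),
                                 pd.Series(np.r_[np.zeros(200), np.ones(200)]),
                                 n_boot=2000, seed=0)
        assert res.diff == pytest.approx(0.0, abs=1e-12)
        assert res.ci_low <= 0.0 <= res.ci_high

    def test_degenerate_bca_equals_percentile_interval(self):
        rng = np.random.default_rng(11)
        boot = rng.normal(1.0, 0.2, 5000)
        jack = rng.normal(1.0, 0.05, 100)
        lo, hi = bca_interval(boot, 1.0, jack, z0=0.0, accel=0.0)
        assert lo == pytest.approx(np.quantile(boot, 0.025))
        assert hi == pytest.approx(np.quantile(boot, 0.975))

    def test_matches_scipy_bca_on_one_sample_mean(self):
        """Cross-check against an independent BCa implementation."""
        rng = np.random.default_rng(12)
        x = rng.exponential(2.0, 80)   # skewed, so BCa differs from percentile
        n_boot = 4000
        idx = np.random.default_rng(1).integers(0, len(x), size=(n_boot, len(x)))
        boot = x[idx].mean(axis=1)
        jack = (x.sum() - x) / (len(x) - 1)
        lo, hi = bca_interval(boot, float(x.mean()), jack)
        ref = sps.bootstrap((x,), np.mean, n_resamples=n_boot, method="BCa",
                            confidence_level=0.95, random_state=2)
        assert lo == pytest.approx(ref.confidence_interval.low, rel=0.05)
        assert hi == pytest.approx(ref.confidence_interval.high, rel=0.05)

    def test_healthy_sd_units(self):
        rng = np.random.default_rng(13)
        g0 = rng.normal(0, 1, 100)
        g1 = rng.normal(3, 1, 100)
        res = group_contrast_bca(pd.Series(np.r_[g0, g1]),
                                 pd.Series(np.r_[np.zeros(100), np.ones(100)]),
                                 healthy_sd=2.0, n_boot=2000, seed=1)
        assert res.diff_sd == pytest.approx(res.diff / 2.0)
        assert res.ci_low < res.diff < res.ci_high

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            group_contrast_bca(pd.Series([1.0, 2.0, 3.0]),
                               pd.Series([0.0, 0.0, 1.0]), n_boot=100)
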