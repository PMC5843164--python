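import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu

import gaitpheno as gp
from gaitpheno.forests import (
    CLINICAL_MTRY_GRID,
    ForestSpec,
    _fit_forest,
    fit_clinical_forest,
    fit_mild_vs_healthy_forest,
    fit_pattern_forest,
    oob_error_rate,
    oob_predictions,
    permutation_vimp,
    tree_oob_masks,
)

NAMES_20 = [f"f{j}" for j in range(20)]


@pytest.fixture(scope="module")
def gaussian_design():
    rng = np.random.default_rng(123)
    X = rng.standard_normal((250, 20))
    return X


class TestOobMachinery:
    def test_oob_votes_match_sklearn_oob_decision_function(self, gaussian_design):
        """Our per-tree OOB bookkeeping reproduces sklearn's own OOB votes."""
        X = gaussian_design
        y = (X[:, 3] + 0.5 * X[:, 7] > 0).astype(int)
        from sklearn.ensemble import RandomForestClassifier
        forest = RandomForestClassifier(n_estimators=150, max_features=4,
                                        oob_score=True, random_state=7, n_jobs=1)
        forest.fit(X, y)
        ours = oob_predictions(forest, X)
        assert np.allclose(ours, forest.oob_decision_function_, atol=1e-12, equal_nan=True)

    def test_oob_masks_exclude_bootstrap_rows(self, gaussian_design):
        X = gaussian_design
        y = (X[:, 0] > 0).astype(int)
        forest = _fit_forest(X, y, "classification", 4, 25, 0)
        masks = tree_oob_masks(forest, len(X))
        # roughly 1/e of samples OOB per tree
        frac = masks.mean()
        assert 0.25 < frac < 0.45


class TestPatternForest:
    def test_planted_feature_ranks_first_and_oob_near_zero(self, gaussian_design):
        X = pd.DataFrame(gaussian_design, columns=NAMES_20)
        y = pd.Series((X["f5"] > 0).astype(float).to_numpy(), index=X.index)
        spec = ForestSpec(task="classification", n_trees=200, mtry_grid=(4,), seed=0)
        _, report, vimp = fit_pattern_forest(X, y, spec)
        assert report.oob_error <= 0.02
        assert vimp.table.iloc[0]["parameter"] == "f5"

    def test_permuted_labels_are_chance_level(self, gaussian_design):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(gaussian_design, columns=NAMES_20)
        y = pd.Series(rng.permutation((X["f5"] > 0.4).astype(float).to_numpy()),
                      index=X.index)
        spec = ForestSpec(task="classification", n_trees=200, mtry_grid=(4,), seed=1)
        _, report, vimp = fit_pattern_forest(X, y, spec)
        chance = 1.0 - max(y.mean(), 1 - y.mean())
        assert report.oob_error == pytest.approx(chance, abs=0.1)
        assert abs(vimp.table["vimp"].mean()) < 0.01

    def test_single_class_rejected(self, gaussian_design):
        X = pd.DataFrame(gaussian_design, columns=NAMES_20)
        y = pd.Series(np.zeros(len(X)), index=X.index)
        with pytest.raises(ValueError):
            fit_pattern_forest(X, y, ForestSpec(task="classification", n_trees=10))

    def test_nan_labels_excluded_from_training(self, gaussian_design):
        X = pd.DataFrame(gaussian_design, columns=NAMES_20)
        y = pd.Series((X["f5"] > 0).astype(float).to_numpy(), index=X.index)
        y.iloc[0] = np.nan
        spec = ForestSpec(task="classification", n_trees=50, mtry_grid=(4,), seed=0)
        _, report, _ = fit_pattern_forest(X, y, spec)
        assert report.n_used == len(X) - 1
        assert report.n_dropped == 1


class TestMildVsHealthy:
    def test_separable_groups_auc_near_one(self, gaussian_design):
        X = pd.DataFrame(gaussian_design, columns=NAMES_20)
        mild = X.iloc[:100].copy()
        mild["f2"] = mild["f2"] + 10.0
        healthy = X.iloc[100:]
        spec = ForestSpec(task="regression", n_trees=150, mtry_grid=(4,), seed=0)
        _, report, vimp, curves = fit_mild_vs_healthy_forest(mild, healthy, spec)
        assert report.auc > 0.97
        assert vimp.table.iloc[0]["parameter"] == "f2"
        assert set(curves) == set(vimp.top(6))

    def test_identical_distributions_auc_chance(self, gaussian_design):
        X = pd.DataFrame(gaussian_design, columns=NAMES_20)
        spec = ForestSpec(task="regression", n_trees=150, mtry_grid=(4,), seed=0)
        _, report, _, _ = fit_mild_vs_healthy_forest(X.iloc[:125], X.iloc[125:], spec)
        assert report.auc == pytest.approx(0.5, abs=0.12)

    def test_oob_auc_equals_rank_statistic(self, gaussian_design):
        """AUC of OOB scores equals the Mann-Whitney U statistic on them."""
        X = pd.DataFrame(gaussian_design, columns=NAMES_20)
        mild = X.iloc[:100].copy()
        mild["f2"] = mild["f2"] + 2.0
        healthy = X.iloc[100:]
        spec = ForestSpec(task="regression", n_trees=150, mtry_grid=(4,), seed=3)
        model, report, _, _ = fit_mild_vs_healthy_forest(mild, healthy, spec)
        frame = pd.concat([healthy, mild])
        scores = oob_predictions(model, frame.to_numpy(float))
        y = np.r_[np.zeros(len(healthy)), np.ones(len(mild))]
        u = mannwhitneyu(scores[y == 1], scores[y == 0]).statistic
        assert report.auc == pytest.approx(u / (y.sum() * (len(y) - y.sum())))

    def test_mild_pattern_marginal_curve_rises_after_75pct(self):
        """On a cohort planted with the mild-pattern signature, the
        time-to-peak-knee-flexion marginal effect is higher past ~75% of the
        cycle than before it."""
        cycles, _, truth = gp.generate_cohort(gp.CohortConfig(n_subjects=14, seed=5))
        h_cycles, _ = gp.generate_healthy_cohort(n_subjects=12, seed=6)
        pm, hpm = gp.extract_matrix(cycles), gp.extract_matrix(h_cycles)
        mild_ids = truth.loc[truth["pattern"] == "I", "cycle_id"]
        spec = ForestSpec(task="regression", n_trees=200, mtry_grid=(1, 14), seed=7)
        model, report, _, _ = fit_mild_vs_healthy_forest(pm.loc[mild_ids], hpm, spec)
        assert report.auc > 0.9
        from gaitpheno.forests import marginal_effect_curves
        curve = marginal_effect_curves(model, pd.concat([hpm, pm.loc[mild_ids]]),
                                       ["time_to_peak_knee_flexion"])["time_to_peak_knee_flexion"]
        early = curve.loc[curve["x"] < 72.0, "smoothed"].mean()
        late = curve.loc[curve["x"] > 75.0, "smoothed"].mean()
        assert late > early


class TestClinicalForest:
    def test_planted_age_dependence(self, gaussian_design):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(gaussian_design, columns=NAMES_20)
        age = pd.Series(rng.uniform(4, 17, len(X)), index=X.index)
        X = X.copy()
        X["f9"] = 2.0 - 0.3 * age + rng.normal(0, 0.3, len(X))
        spec = ForestSpec(task="regression", n_trees=200, mtry_grid=(4,), seed=0)
        _, report, vimp = fit_clinical_forest(X, age, "quantitative", spec)
        assert report.rho > 0.8
        assert vimp.table.iloc[0]["parameter"] == "f9"

    def test_independent_binary_target_chance_auc(self, gaussian_design):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(gaussian_design, columns=NAMES_20)
        y = pd.Series(rng.integers(0, 2, len(X)).astype(float), index=X.index)
        spec = ForestSpec(task="regression", n_trees=150, mtry_grid=(4,), seed=0)
        _, report, _ = fit_clinical_forest(X, y, "binary", spec)
        assert report.auc == pytest.approx(0.5, abs=0.12)

    def test_unknowns_dropped_with_count(self, gaussian_design):
        X = pd.DataFrame(gaussian_design, columns=NAMES_20)
        y = pd.Series((X["f0"] > 0).astype(float).to_numpy(), index=X.index)
        y.iloc[:30] = np.nan
        spec = ForestSpec(task="regression", n_trees=50, mtry_grid=(4,), seed=0)
        _, report, _ = fit_clinical_forest(X, y, "binary", spec)
        assert report.n_dropped == 30

    def test_gmfcs_signature_recovered_in_top4(self):
        """Cohort planted with the severity signature (higher knee flexion at
        initial contact + delayed knee-flexion peak in GMFCS II-III): both
        parameters surface in the top-4 VIMP."""
        rng = np.random.default_rng(8)
        base = gp.healthy_template()
        sig = gp.PatternSpec("I", knee_ic_offset=10.0, knee_peak_delay=6.0)
        cycles, labels = [], []
        for i in range(120):
            severe = i % 2 == 1
            bundle = gp.apply_pattern(base, sig, severity=1.0) if severe else base
            channels = {
                name: gp.AngleSeries(channel=name,
                                     values=vals + rng.normal(0, 2.0)
                                     + rng.normal(0, 1.0, size=201))
                for name, vals in bundle.channels.items()
            }
            cycles.append(gp.GaitCycle(
                cycle_id=f"c{i}", subject_id=f"s{i}", side="left", channels=channels,
                events=bundle.events, stride_time=bundle.stride_time,
                stride_length=bundle.stride_length, subject_height=bundle.subject_height))
            labels.append(float(severe))
        pm = gp.extract_matrix(cycles)
        spec = ForestSpec(task="regression", n_trees=300, mtry_grid=CLINICAL_MTRY_GRID, seed=9)
        _, report, vimp = fit_clinical_forest(pm, pd.Series(labels, index=pm.index),
                                              "binary", spec)
        top4 = vimp.top(4)
        assert "knee_flexion_at_initial_contact" in top4
        assert "time_to_peak_knee_flexion" in top4
        assert report.auc > 0.9
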