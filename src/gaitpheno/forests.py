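"""Random-forest layers linking gait patterns, parameters and clinical features.

Three analyses share one machinery:

* classification forests predicting the sagittal pattern of each cycle from
  the 43 interpretable parameters (out-of-bag error as goodness of fit);
* regression forests separating the mildest HSP pattern from healthy cycles
  (0/1 coding, OOB AUC) with unadjusted marginal-effect curves;
* regression forests predicting clinical features (age, sex, GMFCS group,
  polyneuropathy, abnormal VEP, thin corpus callosum) from gait parameters
  (OOB AUC for binary targets, Spearman rho for age).

Variable importance is Breiman-Cutler permutation importance (VIMP): for each
tree, the increase in out-of-bag prediction error when one predictor is
randomly permuted among that tree's OOB cases, averaged over trees.
scikit-learn grows the forests; the per-tree OOB bookkeeping and the
permutation importance are implemented here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.metrics import roc_auc_score
from sklearn.utils import check_random_state

#: mtry grids used by the three analyses.
PATTERN_MTRY_GRID = (1, 3, 6, 12)
MILD_VS_HEALTHY_MTRY_GRID = (1, 14, 29)
CLINICAL_MTRY_GRID = (1, 7, 14, 28)


@dataclass(frozen=True)
class ForestSpec:
    """Forest hyperparameters: task, ensemble size, candidate mtry values, seed.

    Tree-building defaults follow the classic random-forest settings:
    bootstrap samples of size n drawn with replacement, terminal node size 1
    for classification and 5 for regression.
    """

    task: Literal["classification", "regression"]
    n_trees: int = 1000
    mtry_grid: tuple[int, ...] = PATTERN_MTRY_GRID
    seed: int = 0

    def __post_init__(self) -> None:
        if self.task not in ("classification", "regression"):
            raise ValueError(f"unknown task {self.task!r}")
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if any(m < 1 for m in self.mtry_grid):
            raise ValueError("mtry values must be >= 1")


@dataclass
class ImportanceTable:
    """Permutation importances, one entry per predictor, ranked descending."""

    table: pd.DataFrame  # columns: parameter, vimp (sorted by vimp desc)

    def top(self, n: int) -> list[str]:
        return list(self.table["parameter"].head(n))

    @classmethod
    def from_values(cls, names: Sequence[str], vimp: np.ndarray) -> "ImportanceTable":
        frame = pd.DataFrame({"parameter": list(names), "vimp": vimp})
        frame = frame.sort_values("vimp", ascending=False, kind="mergesort").reset_index(drop=True)
        return cls(table=frame)


@dataclass
class FitReport:
    """Goodness of fit of the best forest over the mtry grid."""

    task: str
    best_mtry: int
    oob_error: float | None = None
    per_class_error: pd.Series | None = None
    confusion: pd.DataFrame | None = None
    auc: float | None = None
    rho: float | None = None
    n_used: int = 0
    n_dropped: int = 0
    grid_scores: dict[int, float] = field(default_factory=dict)


def _fit_forest(X: np.ndarray, y: np.ndarray, task: str, mtry: int,
                n_trees: int, seed: int):
    common = dict(
        n_estimators=n_trees,
        max_features=min(mtry, X.shape[1]),
        bootstrap=True,
        random_state=seed,
        n_jobs=1,
    )
    if task == "classification":
        model = RandomForestClassifier(min_samples_leaf=1, **common)
    else:
        model = RandomForestRegressor(min_samples_leaf=5, **common)
    model.fit(X, y)
    return model


def _tree_sample_indices(tree, n: int) -> np.ndarray:
    """Reconstruct a tree's bootstrap sample (mirrors the forest's own draw)."""
    rng = check_random_state(tree.random_state)
    return rng.randint(0, n, n)


def tree_oob_masks(forest, n: int) -> np.ndarray:
    """Boolean (n_trees, n) matrix: True where sample i is out of bag for tree t."""
    masks = np.ones((len(forest.estimators_), n), dtype=bool)
    for t, tree in enumerate(forest.estimators_):
        masks[t, _tree_sample_indices(tree, n)] = False
    return masks


def oob_predictions(forest, X: np.ndarray) -> np.ndarray:
    """Per-sample OOB prediction: vote fraction / mean over trees where OOB.

    Classification returns the OOB probability of each class (n, n_classes);
    regression returns the mean OOB prediction (n,).  Samples never OOB get
    the overall prior/mean (rare for >= 100 trees).
    """
    n = X.shape[0]
    masks = tree_oob_masks(forest, n)
    if hasattr(forest, "classes_"):
        k = len(forest.classes_)
        votes = np.zeros((n, k))
        counts = np.zeros(n)
        for t, tree in enumerate(forest.estimators_):
            oob = masks[t]
            if not oob.any():
                continue
            votes[oob] += tree.predict_proba(X[oob])
            counts[oob] += 1
        never = counts == 0
        votes[never] = 1.0 / k
        counts[never] = 1.0
        return votes / counts[:, None]
    preds = np.zeros(n)
    counts = np.zeros(n)
    for t, tree in enumerate(forest.estimators_):
        oob = masks[t]
        if not oob.any():
            continue
        preds[oob] += tree.predict(X[oob])
        counts[oob] += 1
    never = counts == 0
    if never.any():
        preds[never] = forest.predict(X[never]) * 1.0
        counts[never] = 1.0
    return preds / counts


def oob_error_rate(forest, X: np.ndarray, y: np.ndarray) -> float:
    """OOB misclassification rate of a classification forest."""
    proba = oob_predictions(forest, X)
    pred = forest.classes_[np.argmax(proba, axis=1)]
    return float(np.mean(pred != y))


def permutation_vimp(forest, X: np.ndarray, y: np.ndarray,
                     names: Sequence[str], seed: int = 0) -> ImportanceTable:
    """Breiman-Cutler VIMP: per-tree OOB error increase under permutation."""
    rng = np.random.default_rng(seed)
    n, p = X.shape
    masks = tree_oob_masks(forest, n)
    is_clf = hasattr(forest, "classes_")

    def tree_error(tree, Xs, ys):
        if is_clf:
            # sub-estimators predict class indices into forest.classes_
            pred = forest.classes_[tree.predict(Xs).astype(int)]
            return np.mean(pred != ys)
        return np.mean((tree.predict(Xs) - ys) ** 2)

    deltas = np.zeros((len(forest.estimators_), p))
    for t, tree in enumerate(forest.estimators_):
        oob = np.flatnonzero(masks[t])
        if oob.size == 0:
            continue
        Xo, yo = X[oob], y[oob]
        base = tree_error(tree, Xo, yo)
        for j in range(p):
            Xp = Xo.copy()
            Xp[:, j] = Xo[rng.permutation(oob.size), j]
            deltas[t, j] = tree_error(tree, Xp, yo) - base
    return ImportanceTable.from_values(names, deltas.mean(axis=0))


def fit_pattern_forest(params: pd.DataFrame, labels: pd.Series,
                       spec: ForestSpec | None = None):
    """Classify cycles into sagittal patterns from the 43 parameters.

    ``labels`` is indexed by cycle_id; rows flagged NaN (or labelled as
    outliers by the caller dropping them beforehand) are excluded from
    training.  Returns (model, FitReport, ImportanceTable).
    """
    spec = spec or ForestSpec(task="classification", mtry_grid=PATTERN_MTRY_GRID)
    if spec.task != "classification":
        raise ValueError("pattern forest requires a classification spec")
    y = labels.reindex(params.index)
    keep = y.notna()
    X = params.loc[keep].to_numpy(dtype=float)
    yv = y.loc[keep].to_numpy()
    if len(np.unique(yv)) < 2:
        raise ValueError("need at least two pattern classes to train")
    ss = np.random.SeedSequence(spec.seed)
    seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(len(spec.mtry_grid))]
    best = None
    grid_scores: dict[int, float] = {}
    for mtry, seed in zip(spec.mtry_grid, seeds):
        model = _fit_forest(X, yv, "classification", mtry, spec.n_trees, seed)
        err = oob_error_rate(model, X, yv)
        grid_scores[mtry] = err
        if best is None or err < best[1]:
            best = (model, err, mtry, seed)
    model, err, mtry, seed = best
    proba = oob_predictions(model, X)
    pred = model.classes_[np.argmax(proba, axis=1)]
    confusion = pd.crosstab(pd.Series(yv, name="true"), pd.Series(pred, name="predicted"))
    per_class = pd.Series(
        {c: float(np.mean(pred[yv == c] != c)) for c in model.classes_}, name="error"
    )
    report = FitReport(task="classification", best_mtry=mtry, oob_error=err,
                       per_class_error=per_class, confusion=confusion,
                       n_used=int(keep.sum()), n_dropped=int((~keep).sum()),
                       grid_scores=grid_scores)
    vimp = permutation_vimp(model, X, yv, list(params.columns), seed=seed)
    return model, report, vimp


def _running_mean(x: np.ndarray, y: np.ndarray, frac: float = 0.1) -> np.ndarray:
    """Centered running mean of y over x-sorted data; window = frac of n."""
    n = len(x)
    w = max(3, int(round(frac * n)))
    half = w // 2
    out = np.empty(n)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        out[i] = y[lo:hi].mean()
    return out


def marginal_effect_curves(model, X: pd.DataFrame, top_params: Sequence[str],
                           smoother_frac: float = 0.1) -> dict[str, pd.DataFrame]:
    """Unadjusted marginal effects: OOB prediction vs raw parameter value.

    For each requested parameter, the scatter of the OOB response estimate
    against the observed parameter value, plus a running-mean smoother
    (window = ``smoother_frac`` of the data).  This is the unadjusted view,
    not a partial-dependence computation.
    """
    yhat = oob_predictions(model, X.to_numpy(dtype=float))
    curves = {}
    for name in top_params:
        x = X[name].to_numpy(dtype=float)
        order = np.argsort(x, kind="mergesort")
        frame = pd.DataFrame({
            "x": x[order],
            "yhat": yhat[order],
        })
        frame["smoothed"] = _running_mean(frame["x"].to_numpy(), frame["yhat"].to_numpy(),
                                          smoother_frac)
        curves[name] = frame
    return curves


def fit_mild_vs_healthy_forest(params_mild: pd.DataFrame, params_healthy: pd.DataFrame,
                               spec: ForestSpec | None = None, n_marginal: int = 6):
    """Regression forest separating mild-pattern HSP cycles (1) from healthy (0).

    Returns (model, FitReport, ImportanceTable, marginal-effect curves).
    """
    spec = spec or ForestSpec(task="regression", mtry_grid=MILD_VS_HEALTHY_MTRY_GRID)
    if params_mild.empty or params_healthy.empty:
        raise ValueError("both groups must be non-empty")
    X_frame = pd.concat([params_healthy, params_mild], axis=0)
    y = np.concatenate([np.zeros(len(params_healthy)), np.ones(len(params_mild))])
    X = X_frame.to_numpy(dtype=float)
    ss = np.random.SeedSequence(spec.seed)
    seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(len(spec.mtry_grid))]
    best = None
    grid_scores: dict[int, float] = {}
    for mtry, seed in zip(spec.mtry_grid, seeds):
        model = _fit_forest(X, y, "regression", mtry, spec.n_trees, seed)
        auc = float(roc_auc_score(y, oob_predictions(model, X)))
        grid_scores[mtry] = auc
        if best is None or auc > best[1]:
            best = (model, auc, mtry, seed)
    model, auc, mtry, seed = best
    report = FitReport(task="regression", best_mtry=mtry, auc=auc,
                       n_used=len(y), grid_scores=grid_scores)
    vimp = permutation_vimp(model, X, y, list(X_frame.columns), seed=seed)
    curves = marginal_effect_curves(model, X_frame, vimp.top(n_marginal))
    return model, report, vimp, curves


def fit_clinical_forest(params: pd.DataFrame, target: pd.Series,
                        kind: Literal["binary", "quantitative"],
                        spec: ForestSpec | None = None):
    """Regression forest predicting one clinical feature from gait parameters.

    Binary targets are 0/1-coded; rows with missing target are dropped (the
    report counts them).  Goodness of fit: OOB AUC (binary) or OOB Spearman
    rho (quantitative).  Returns (model, FitReport, ImportanceTable).
    """
    spec = spec or ForestSpec(task="regression", mtry_grid=CLINICAL_MTRY_GRID)
    y = pd.to_numeric(target.reindex(params.index), errors="coerce")
    keep = y.notna()
    if not keep.any():
        raise ValueError("target is unknown for every cycle")
    X = params.loc[keep].to_numpy(dtype=float)
    yv = y.loc[keep].to_numpy(dtype=float)
    if kind == "binary" and len(np.unique(yv)) < 2:
        raise ValueError("binary target has a single class after dropping unknowns")
    ss = np.random.SeedSequence(spec.seed)
    seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(len(spec.mtry_grid))]
    best = None
    grid_scores: dict[int, float] = {}
    for mtry, seed in zip(spec.mtry_grid, seeds):
        model = _fit_forest(X, yv, "regression", mtry, spec.n_trees, seed)
        oob = oob_predictions(model, X)
        if kind == "binary":
            score = float(roc_auc_score(yv, oob))
        else:
            score = float(spearmanr(yv, oob).statistic)
        grid_scores[mtry] = score
        if best is None or score > best[1]:
            best = (model, score, mtry, seed)
    model, score, mtry, seed = best
    report = FitReport(task="regression", best_mtry=mtry,
                       auc=score if kind == "binary" else None,
                       rho=score if kind == "quantitative" else None,
                       n_used=int(keep.sum()), n_dropped=int((~keep).sum()),
                       grid_scores=grid_scores)
    vimp = permutation_vimp(model, X, yv, list(params.columns), seed=seed)
    return model, report, vimp
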