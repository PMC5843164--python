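"""Classical statistics for gait cohorts.

* Z-scores of gait parameters against a healthy reference (per-parameter mean
  and SD over the healthy cohort's cycles);
* Gaussian linear mixed models per spatio-temporal parameter with the sagittal
  pattern as fixed effect and the subject as random intercept, tested by a
  likelihood-ratio test (full maximum likelihood, not REML, because the LRT
  compares fixed-effect structures);
* linear / logistic models relating clinical features to pattern membership,
  with the most common pattern as the dummy-coding reference;
* robust MM-estimator regressions of a gait parameter on age, condition and
  their interaction (high-breakdown S-estimate refined by a bounded-influence
  bisquare M-step);
* group contrasts of means with bias-corrected and accelerated (BCa)
  bootstrap confidence intervals, in raw units and healthy-SD units.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf


# ---------------------------------------------------------------------------
# Healthy reference and Z-scores
# ---------------------------------------------------------------------------

@dataclass
class HealthyReference:
    """Per-parameter mean and SD of the healthy cohort's cycles."""

    mean: pd.Series
    sd: pd.Series

    def __post_init__(self) -> None:
        if not self.mean.index.equals(self.sd.index):
            raise ValueError("mean and sd must cover the same parameters")

    @classmethod
    def from_matrix(cls, healthy_params: pd.DataFrame) -> "HealthyReference":
        return cls(mean=healthy_params.mean(axis=0), sd=healthy_params.std(axis=0, ddof=1))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"mean": self.mean, "sd": self.sd})


def zscore_matrix(params: pd.DataFrame, ref: HealthyReference) -> pd.DataFrame:
    """Standardize every column against the healthy reference: (v - mean)/sd."""
    missing = [c for c in params.columns if c not in ref.mean.index]
    if missing:
        raise ValueError(f"reference does not cover columns {missing}")
    zero = [c for c in params.columns if ref.sd[c] == 0]
    if zero:
        raise ValueError(f"healthy SD is zero for columns {zero}")
    return (params - ref.mean[params.columns]) / ref.sd[params.columns]


# ---------------------------------------------------------------------------
# Linear mixed models with likelihood-ratio tests
# ---------------------------------------------------------------------------

@dataclass
class MixedModelResult:
    """LRT of the pattern fixed effect in a random-intercept model."""

    parameter: str
    lrt_statistic: float
    df: int
    p_value: float
    fixed_effects: pd.Series
    subject_variance: float
    converged: bool
    singular: bool


def fit_pattern_lmm(values: pd.Series, patterns: pd.Series,
                    subjects: pd.Series, parameter: str = "") -> MixedModelResult:
    """One spatio-temporal parameter ~ pattern (fixed) + subject (random intercept).

    All three series are aligned on the cycle index.  Fit by full ML; the LRT
    compares against the intercept-only mixed model, df = pattern levels - 1.
    """
    frame = pd.DataFrame({
        "y": pd.to_numeric(values, errors="coerce"),
        "pattern": patterns.astype(str),
        "subject": subjects.astype(str),
    }).dropna()
    levels = sorted(frame["pattern"].unique())
    if len(levels) < 2:
        raise ValueError("need >= 2 pattern levels")
    if frame["subject"].nunique() < 2:
        raise ValueError("need >= 2 subjects")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        full = smf.mixedlm("y ~ C(pattern)", frame, groups=frame["subject"]).fit(reml=False)
        null = smf.mixedlm("y ~ 1", frame, groups=frame["subject"]).fit(reml=False)
    lrt = max(0.0, 2.0 * (full.llf - null.llf))
    df = len(levels) - 1
    p = float(sps.chi2.sf(lrt, df))
    singular = bool(full.cov_re.iloc[0, 0] < 1e-10)
    return MixedModelResult(
        parameter=parameter,
        lrt_statistic=float(lrt),
        df=df,
        p_value=p,
        fixed_effects=full.fe_params,
        subject_variance=float(full.cov_re.iloc[0, 0]),
        converged=bool(full.converged),
        singular=singular,
    )


def fit_spatiotemporal_lmms(spatiotemporal: pd.DataFrame, patterns: pd.Series,
                            subjects: pd.Series) -> pd.DataFrame:
    """One mixed model per spatio-temporal column; tidy LRT table."""
    rows = []
    for col in spatiotemporal.columns:
        res = fit_pattern_lmm(spatiotemporal[col], patterns, subjects, parameter=col)
        rows.append({
            "parameter": col,
            "lrt_chi2": res.lrt_statistic,
            "df": res.df,
            "p_value": res.p_value,
            "subject_variance": res.subject_variance,
            "converged": res.converged,
            "singular": res.singular,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Clinical feature ~ pattern models
# ---------------------------------------------------------------------------

def fit_clinical_vs_pattern(feature: pd.Series, patterns: pd.Series,
                            kind: str, reference: int | str | None = None) -> pd.DataFrame:
    """Model a clinical feature on dummy-coded pattern membership.

    ``kind="quantitative"``: linear model, per-pattern offsets vs the
    reference pattern plus an overall ANOVA F-test.  ``kind="binary"``:
    logistic model; per-pattern odds ratios vs the reference.  The reference
    defaults to the most common pattern.  Perfect separation is reported with
    an ``infinite_or`` flag instead of raising.
    """
    frame = pd.DataFrame({
        "y": pd.to_numeric(feature, errors="coerce"),
        "pattern": patterns.astype(str),
    }).dropna()
    if reference is None:
        reference = frame["pattern"].value_counts().idxmax()
    reference = str(reference)
    levels = [reference] + sorted(l for l in frame["pattern"].unique() if l != reference)
    frame["pattern"] = pd.Categorical(frame["pattern"], categories=levels)
    rows = []
    if kind == "quantitative":
        model = smf.ols("y ~ C(pattern)", frame).fit()
        anova = sm.stats.anova_lm(model, typ=2)
        f_p = float(anova.loc["C(pattern)", "PR(>F)"])
        for level in levels[1:]:
            term = f"C(pattern)[T.{level}]"
            rows.append({
                "pattern": level, "reference": reference,
                "estimate": float(model.params[term]),
                "ci_low": float(model.conf_int().loc[term, 0]),
                "ci_high": float(model.conf_int().loc[term, 1]),
                "p_value": float(model.pvalues[term]),
                "anova_p": f_p, "infinite_or": False,
            })
    elif kind == "binary":
        separated = {
            level: sub["y"].nunique() < 2
            for level, sub in frame.groupby("pattern", observed=True)
        }
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.glm("y ~ C(pattern)", frame, family=sm.families.Binomial()).fit()
        for level in levels[1:]:
            term = f"C(pattern)[T.{level}]"
            coef = float(model.params[term])
            flagged = separated.get(level, False) or separated.get(reference, False) \
                or abs(coef) > 15
            ci = model.conf_int().loc[term]
            with np.errstate(over="ignore"):
                or_est, or_lo, or_hi = np.exp(coef), np.exp(ci[0]), np.exp(ci[1])
            rows.append({
                "pattern": level, "reference": reference,
                "estimate": float(or_est),
                "ci_low": float(or_lo),
                "ci_high": float(or_hi),
                "p_value": float(model.pvalues[term]),
                "anova_p": np.nan, "infinite_or": bool(flagged),
            })
    else:
        raise ValueError(f"kind must be quantitative|binary, got {kind!r}")
    return pd.DataFrame(rows)


def binarize_gmfcs(gmfcs: pd.Series) -> pd.Series:
    """GMFCS I -> 0; II and III pooled -> 1."""
    mapping = {"I": 0.0, "II": 1.0, "III": 1.0}
    return gmfcs.map(mapping)


# ---------------------------------------------------------------------------
# Robust MM regression
# ---------------------------------------------------------------------------

def _bisquare_rho(u: np.ndarray, c: float) -> np.ndarray:
    w = np.clip(u / c, -1.0, 1.0)
    return (c ** 2 / 6.0) * (1.0 - (1.0 - w ** 2) ** 3)


def _bisquare_weight(u: np.ndarray, c: float) -> np.ndarray:
    out = np.zeros_like(u)
    inside = np.abs(u) < c
    out[inside] = (1.0 - (u[inside] / c) ** 2) ** 2
    return out


def _m_scale(resid: np.ndarray, c: float = 1.547, b: float = 0.5,
             tol: float = 1e-9, max_iter: int = 200) -> float:
    """M-estimate of scale solving mean(rho(r/s)/rho(inf)) = b (50% breakdown)."""
    s = np.median(np.abs(resid)) / 0.6745
    if s <= 0:
        return 0.0
    rho_inf = c ** 2 / 6.0
    for _ in range(max_iter):
        m = np.mean(_bisquare_rho(resid / s, c)) / rho_inf
        s_new = s * np.sqrt(m / b)
        if abs(s_new - s) <= tol * s:
            return s_new
        s = s_new
    return s


def _irls(X: np.ndarray, y: np.ndarray, beta: np.ndarray, scale: float,
          c: float, tol: float = 1e-10, max_iter: int = 200) -> np.ndarray:
    for _ in range(max_iter):
        r = y - X @ beta
        w = _bisquare_weight(r / scale, c)
        if w.sum() <= 0:
            return beta
        Xw = X * w[:, None]
        beta_new, *_ = np.linalg.lstsq(Xw.T @ X, Xw.T @ y, rcond=None)
        if np.max(np.abs(beta_new - beta)) <= tol * (1 + np.max(np.abs(beta))):
            return beta_new
        beta = beta_new
    return beta


@dataclass
class RobustFit:
    """MM regression fit: coefficients, 95% CIs, p-values, robust scale."""

    names: list[str]
    coef: np.ndarray
    se: np.ndarray
    scale: float

    def to_frame(self) -> pd.DataFrame:
        z = self.coef / self.se
        return pd.DataFrame({
            "term": self.names,
            "estimate": self.coef,
            "se": self.se,
            "ci_low": self.coef - 1.959964 * self.se,
            "ci_high": self.coef + 1.959964 * self.se,
            "p_value": 2.0 * sps.norm.sf(np.abs(z)),
        })


def mm_regression(X: np.ndarray, y: np.ndarray, names: list[str] | None = None,
                  n_subsets: int = 200, seed: int = 0,
                  c_s: float = 1.547, c_m: float = 4.685) -> RobustFit:
    """MM-estimator: S-estimate by elemental subsampling, then bisquare M-step.

    The S-stage draws random p-point elemental fits and keeps the one with the
    smallest 50%-breakdown M-scale of residuals (refined by IRLS at the
    S-tuning constant).  The M-stage re-fits with the efficient bisquare
    constant ``c_m = 4.685`` (95% Gaussian efficiency) holding the robust
    scale fixed.  Standard errors use the standard MM asymptotic variance.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if names is None:
        names = [f"x{j}" for j in range(p)]
    rng = np.random.default_rng(seed)
    # include the LS fit as one candidate (helps on clean data)
    candidates = [np.linalg.lstsq(X, y, rcond=None)[0]]
    for _ in range(n_subsets):
        idx = rng.choice(n, size=p, replace=False)
        try:
            beta = np.linalg.solve(X[idx], y[idx])
        except np.linalg.LinAlgError:
            continue
        candidates.append(beta)
    scored = []
    for beta in candidates:
        s = _m_scale(y - X @ beta, c=c_s)
        if s > 0:
            scored.append((s, beta))
    if not scored:
        raise ValueError("S-stage failed: all elemental fits singular")
    scored.sort(key=lambda t: t[0])
    # fast-S style: fully refine the best few candidates (alternating IRLS and
    # scale updates at the 50%-breakdown constant) and keep the smallest scale
    best_beta, best_scale = None, np.inf
    for s, beta in scored[:10]:
        for _ in range(30):
            beta_new = _irls(X, y, beta, s, c_s, max_iter=5)
            s_new = _m_scale(y - X @ beta_new, c=c_s)
            if abs(s_new - s) <= 1e-10 * s and np.allclose(beta_new, beta, atol=1e-12):
                beta, s = beta_new, s_new
                break
            beta, s = beta_new, s_new
        if s < best_scale:
            best_scale, best_beta = s, beta
    scale = best_scale
    beta = _irls(X, y, best_beta, scale, c_m)
    # asymptotic covariance: s^2 * E[psi^2]/E[psi']^2 * (X'X)^-1
    u = (y - X @ beta) / scale
    psi = u * _bisquare_weight(u, c_m)
    inside = np.abs(u) < c_m
    psi_prime = np.zeros_like(u)
    ui = u[inside]
    psi_prime[inside] = (1 - (ui / c_m) ** 2) * (1 - 5 * (ui / c_m) ** 2)
    a = np.mean(psi ** 2)
    b = np.mean(psi_prime)
    if b <= 0:
        b = 1e-6
    cov = (scale ** 2) * (a / b ** 2) * np.linalg.inv(X.T @ X) * n / max(n - p, 1)
    se = np.sqrt(np.diag(cov))
    return RobustFit(names=list(names), coef=beta, se=se, scale=float(scale))


def robust_age_regression(values: pd.Series, age: pd.Series,
                          condition: pd.Series, seed: int = 0) -> RobustFit:
    """parameter ~ age + condition + age x condition, MM robust fit.

    ``condition`` is coded 0 = healthy, 1 = HSP (strings "healthy"/"HSP"
    accepted).  The age slope is the healthy-group slope; the interaction is
    the additional slope in HSP.
    """
    cond = condition.map({"healthy": 0.0, "HSP": 1.0}).astype(float) \
        if condition.dtype == object else condition.astype(float)
    frame = pd.DataFrame({
        "y": pd.to_numeric(values, errors="coerce"),
        "age": pd.to_numeric(age, errors="coerce"),
        "cond": cond,
    }).dropna()
    for level in (0.0, 1.0):
        if (frame["cond"] == level).sum() < 10:
            raise ValueError("need >= 10 observations per condition")
    X = np.column_stack([
        np.ones(len(frame)), frame["age"], frame["cond"], frame["age"] * frame["cond"],
    ])
    return mm_regression(X, frame["y"].to_numpy(),
                         names=["intercept", "age", "condition", "age:condition"],
                         seed=seed)


# ---------------------------------------------------------------------------
# BCa bootstrap group contrasts
# ---------------------------------------------------------------------------

@dataclass
class ContrastResult:
    """Two-group mean difference with 95% BCa CIs, raw and healthy-SD units."""

    parameter: str
    grouping: str
    diff: float
    ci_low: float
    ci_high: float
    diff_sd: float
    ci_low_sd: float
    ci_high_sd: float
    n_group1: int
    n_group0: int

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def bca_interval(boot: np.ndarray, theta_hat: float, jack: np.ndarray,
                 alpha: float = 0.05,
                 z0: float | None = None, accel: float | None = None) -> tuple[float, float]:
    """BCa interval from bootstrap replicates and jackknife leave-one-out values.

    ``z0`` (bias correction) defaults to the normal quantile of the fraction
    of bootstrap replicates below the point estimate; ``accel`` defaults to
    the jackknife skewness estimate.  Passing ``z0 = accel = 0`` reduces the
    interval to the plain percentile interval.
    """
    boot = np.asarray(boot, dtype=float)
    if z0 is None:
        frac = np.mean(boot < theta_hat) + 0.5 * np.mean(boot == theta_hat)
        frac = min(max(frac, 1e-12), 1 - 1e-12)
        z0 = float(sps.norm.ppf(frac))
    if accel is None:
        d = jack.mean() - jack
        denom = 6.0 * (d ** 2).sum() ** 1.5
        accel = float((d ** 3).sum() / denom) if denom > 0 else 0.0
    z_lo, z_hi = sps.norm.ppf(alpha / 2), sps.norm.ppf(1 - alpha / 2)
    a_lo = sps.norm.cdf(z0 + (z0 + z_lo) / (1 - accel * (z0 + z_lo)))
    a_hi = sps.norm.cdf(z0 + (z0 + z_hi) / (1 - accel * (z0 + z_hi)))
    lo, hi = np.quantile(boot, [a_lo, a_hi])
    return float(lo), float(hi)


def group_contrast_bca(values: pd.Series | np.ndarray, groups: pd.Series | np.ndarray,
                       healthy_sd: float | None = None, n_boot: int = 10_000,
                       seed: int = 0, parameter: str = "", grouping: str = "",
                       alpha: float = 0.05) -> ContrastResult:
    """mean(group 1) - mean(group 0) with a 95% BCa bootstrap interval.

    Resampling is within-group at the cycle level.  When ``healthy_sd`` is
    given, the same contrast is also reported in healthy-SD units.
    """
    v = np.asarray(pd.to_numeric(pd.Series(values), errors="coerce"), dtype=float)
    g = np.asarray(pd.Series(groups), dtype=float)
    keep = np.isfinite(v) & np.isfinite(g)
    v, g = v[keep], g[keep]
    x1, x0 = v[g == 1], v[g == 0]
    if len(x1) < 3 or len(x0) < 3:
        raise ValueError("need >= 3 observations in each group")
    theta = float(x1.mean() - x0.mean())
    rng = np.random.default_rng(seed)
    b1 = rng.integers(0, len(x1), size=(n_boot, len(x1)))
    b0 = rng.integers(0, len(x0), size=(n_boot, len(x0)))
    boot = x1[b1].mean(axis=1) - x0[b0].mean(axis=1)
    # jackknife over all observations (leave one out of its own group)
    n1, n0 = len(x1), len(x0)
    s1, s0 = x1.sum(), x0.sum()
    jack1 = (s1 - x1) / (n1 - 1) - x0.mean()
    jack0 = x1.mean() - (s0 - x0) / (n0 - 1)
    jack = np.concatenate([jack1, jack0])
    lo, hi = bca_interval(boot, theta, jack, alpha=alpha)
    if healthy_sd is not None and healthy_sd > 0:
        diff_sd, lo_sd, hi_sd = theta / healthy_sd, lo / healthy_sd, hi / healthy_sd
    else:
        diff_sd = lo_sd = hi_sd = float("nan")
    return ContrastResult(parameter=parameter, grouping=grouping,
                          diff=theta, ci_low=lo, ci_high=hi,
                          diff_sd=diff_sd, ci_low_sd=lo_sd, ci_high_sd=hi_sd,
                          n_group1=len(x1), n_group0=len(x0))
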