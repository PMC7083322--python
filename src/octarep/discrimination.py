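"""Age-adjusted discrimination of healthy vs. pathology eyes.

For each algorithm, layer and metric a binary logistic regression of health
status on (metric value, age) produces fitted probabilities; those feed an
empirical ROC curve.  AUC is computed by the trapezoidal rule (identical to
the tie-aware normalized Mann-Whitney U statistic), its 95% CI by the
Hanley–McNeil standard-error approximation, and paired AUCs are compared
with DeLong's test, which accounts for the correlation between two
probability vectors evaluated on the same eyes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
import statsmodels.api as sm

from .repeatability import StatTestResult


@dataclass
class RocResult:
    auc: float
    ci_low: float
    ci_high: float
    curve: np.ndarray                    # (m, 2) of (FPR, TPR)
    probabilities: np.ndarray
    labels: np.ndarray
    model_coefficients: dict = field(default_factory=dict)
    separation_flag: bool = False
    algorithm: str | None = None
    layer: str | None = None
    metric: str | None = None


def logistic_probability(
    metric_values,
    ages,
    labels,
    ridge: float = 1e-4,
) -> tuple[np.ndarray, dict, bool]:
    """Fit label ~ intercept + metric + age by maximum likelihood.

    Returns (fitted probabilities, coefficient dict, separation flag).  On
    detected complete/quasi-separation the fit is redone with a small L2
    penalty (``ridge``) on the non-intercept coefficients and flagged.
    """
    x = np.asarray(metric_values, dtype=np.float64)
    a = np.asarray(ages, dtype=np.float64)
    y = np.asarray(labels, dtype=np.float64)
    if x.shape != a.shape or x.shape != y.shape or x.ndim != 1:
        raise ValueError("metric_values, ages and labels must be equal-length 1-D")
    if len(y) < 6:
        raise ValueError("need at least 6 observations")
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("both classes must be present")

    # fit on standardized predictors (the metric's natural scale can be
    # ~1e-7, which would otherwise dwarf any fixed penalty or overflow
    # guard); coefficients are reported back on the original scale
    def _standardize(v):
        sd = v.std()
        return (v - v.mean()) / sd if sd > 0 else v - v.mean(), (v.mean(), sd)

    xs, (mx, sx) = _standardize(x)
    as_, (ma, sa) = _standardize(a)
    X = np.column_stack([np.ones_like(xs), xs, as_])
    separated = False
    try:
        # separation and non-convergence are detected below and handled by
        # the penalized refit, so the fit's own warnings are suppressed
        with np.errstate(all="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        probs = np.asarray(fit.predict(X))
        params = np.asarray(fit.params)
        # quasi-separation: essentially perfect fit or exploding coefficients
        if np.all(np.abs(probs - y) < 1e-6) or np.any(np.abs(params[1:]) > 1e4):
            separated = True
    except Exception:
        separated = True

    if separated:
        params = _ridge_logit(X, y, ridge)
        probs = _sigmoid(X @ params)
    b_metric = params[1] / sx if sx > 0 else params[1]
    b_age = params[2] / sa if sa > 0 else params[2]
    intercept = params[0] - b_metric * mx - b_age * ma
    coef = {"intercept": float(intercept), "metric": float(b_metric), "age": float(b_age)}
    return probs, coef, separated


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))


def _ridge_logit(X: np.ndarray, y: np.ndarray, ridge: float) -> np.ndarray:
    """Penalized MLE: -loglik + ridge * ||beta[1:]||^2 (intercept unpenalized)."""

    def objective(beta):
        z = X @ beta
        # log(1 + exp(z)) - y z, numerically stable
        ll = np.sum(np.logaddexp(0.0, z) - y * z)
        return ll + ridge * np.sum(beta[1:] ** 2)

    res = optimize.minimize(objective, np.zeros(X.shape[1]), method="BFGS")
    return res.x


def roc_curve(probabilities, labels, **meta) -> RocResult:
    """Empirical ROC over all cutpoints; trapezoidal AUC (ties count 1/2)."""
    p = np.asarray(probabilities, dtype=np.float64)
    y = np.asarray(labels, dtype=np.float64)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("labels must be binary 0/1")
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")

    order = np.argsort(-p, kind="mergesort")
    ps, ys = p[order], y[order]
    # group equal probabilities into single cutpoints
    distinct = np.r_[True, np.diff(ps) != 0]
    idx = np.flatnonzero(distinct)
    tp = np.cumsum(ys)
    fp = np.cumsum(1.0 - ys)
    block_end = np.r_[idx[1:] - 1, len(ps) - 1]
    tpr = np.r_[0.0, tp[block_end] / n1]
    fpr = np.r_[0.0, fp[block_end] / n0]
    auc = float(np.trapezoid(tpr, fpr))
    curve = np.column_stack([fpr, tpr])
    ci_low, ci_high = hanley_mcneil_ci(auc, n1, n0)
    return RocResult(
        auc=auc, ci_low=ci_low, ci_high=ci_high, curve=curve,
        probabilities=p, labels=y.astype(int), **meta,
    )


def hanley_mcneil_ci(
    auc: float, n_pos: int, n_neg: int, confidence: float = 0.95
) -> tuple[float, float]:
    """Nonparametric AUC CI via the Hanley–McNeil exponential approximation.

    Truncated to [0, 1]; degenerate AUC in {0, 1} collapses the interval
    toward the bound.
    """
    if n_pos < 2 or n_neg < 2:
        raise ValueError("need at least 2 observations per class")
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    var = (
        auc * (1.0 - auc)
        + (n_pos - 1) * (q1 - auc**2)
        + (n_neg - 1) * (q2 - auc**2)
    ) / (n_pos * n_neg)
    se = float(np.sqrt(max(var, 0.0)))
    z = stats.norm.ppf(0.5 + confidence / 2.0)
    return max(0.0, auc - z * se), min(1.0, auc + z * se)


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _delong_structural_components(p: np.ndarray, y: np.ndarray):
    pos, neg = p[y == 1], p[y == 0]
    m, n = len(pos), len(neg)
    all_r = _midrank(np.concatenate([pos, neg]))
    pos_r, neg_r = _midrank(pos), _midrank(neg)
    auc = (all_r[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (all_r[:m] - pos_r) / n            # per-positive components
    v01 = 1.0 - (all_r[m:] - neg_r) / m      # per-negative components
    return auc, v10, v01


def compare_auc(roc_a: RocResult, roc_b: RocResult) -> StatTestResult:
    """Paired DeLong test for two correlated AUCs on the same eyes."""
    ya, yb = roc_a.labels, roc_b.labels
    if len(ya) != len(yb) or not np.array_equal(ya, yb):
        raise ValueError("ROC results must be computed on the same eyes and labels")
    y = np.asarray(ya)
    auc1, v10_1, v01_1 = _delong_structural_components(roc_a.probabilities, y)
    auc2, v10_2, v01_2 = _delong_structural_components(roc_b.probabilities, y)
    m, n = len(v10_1), len(v01_1)
    s10 = np.cov(np.vstack([v10_1, v10_2]))
    s01 = np.cov(np.vstack([v01_1, v01_2]))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (
        s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]
    ) / n
    diff = auc1 - auc2
    if var <= 0:
        z = 0.0 if diff == 0 else np.inf * np.sign(diff)
        p = 1.0 if diff == 0 else 0.0
    else:
        z = diff / np.sqrt(var)
        p = float(2.0 * stats.norm.sf(abs(z)))
    return StatTestResult("DeLong paired AUC", float(z), p)
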