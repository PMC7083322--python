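"""Test–retest agreement statistics for paired vessel-density measurements.

Per algorithm, layer and metric (VD or VSD) the module computes relative
test–retest differences, the intraclass correlation coefficient (two-way
random effects, absolute agreement, single measures — ICC(A,1)) with its
F-based 95% CI, and the repeatability coefficient

    RC = 1.96 * sqrt( sum_i (m2_i - m1_i)^2 / n ).

Inter-algorithm comparisons use the Friedman test with Wilcoxon signed-rank
post-hocs under Holm-Bonferroni correction; group comparisons use
Mann-Whitney-U / Kruskal-Wallis; an age adjustment regresses relative
differences on age plus seven 0/1 algorithm indicators (no separate
intercept — the indicators span it).  A Monte-Carlo power routine for the
Friedman test rounds off the battery.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests
import statsmodels.api as sm


@dataclass(frozen=True)
class PairedMeasurements:
    """Aligned test–retest value pairs for one algorithm/layer/metric."""

    algorithm: str
    layer: str
    metric: str
    pairs: np.ndarray        # (n, 2)

    def __post_init__(self) -> None:
        arr = np.asarray(self.pairs, dtype=np.float64)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValueError("pairs must be an (n, 2) array")
        object.__setattr__(self, "pairs", arr)

    @property
    def n(self) -> int:
        return len(self.pairs)


@dataclass(frozen=True)
class ICCResult:
    icc: float
    ci_low: float
    ci_high: float
    model: str = "two-way random, absolute agreement, single measures (A,1)"
    degenerate: bool = False


@dataclass(frozen=True)
class StatTestResult:
    name: str
    statistic: float
    p: float
    p_corrected: float | None = None


@dataclass(frozen=True)
class RegressionResult:
    params: pd.Series
    pvalues: pd.Series
    conf_int: pd.DataFrame


def relative_difference(m1: float, m2: float) -> float:
    """|m2 - m1| normalized by the pair mean; 0 when both values are 0."""
    mean = (m1 + m2) / 2.0
    if mean == 0.0:
        if m1 == m2 == 0.0:
            return 0.0
        raise ValueError("pair mean is zero but values differ")
    if mean < 0.0:
        raise ValueError("relative difference requires a positive pair mean")
    return abs(m2 - m1) / mean


def repeatability_coefficient(pm: PairedMeasurements | np.ndarray) -> float:
    """RC = 1.96 * sqrt(mean squared test–retest difference)."""
    pairs = pm.pairs if isinstance(pm, PairedMeasurements) else np.asarray(pm, float)
    if len(pairs) == 0:
        raise ValueError("repeatability coefficient needs at least one pair")
    d = pairs[:, 1] - pairs[:, 0]
    return 1.96 * float(np.sqrt(np.mean(d**2)))


def icc_single(pm: PairedMeasurements | np.ndarray, confidence: float = 0.95) -> ICCResult:
    """ICC(A,1): two-way random effects, absolute agreement, single measures.

    Computed from the mean squares of the two-way (subject x measurement)
    decomposition; the CI follows the F-distribution method of McGraw &
    Wong.  Negative estimates are legitimate and returned as-is; data with
    no variance at all are flagged degenerate with ICC undefined (nan).
    """
    data = pm.pairs if isinstance(pm, PairedMeasurements) else np.asarray(pm, float)
    n, k = data.shape
    if n < 3:
        raise ValueError("ICC needs at least 3 subjects")
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)

    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols

    msr = ss_rows / (n - 1)                  # between-subject
    msc = ss_cols / (k - 1)                  # between-measurement
    mse = ss_err / ((n - 1) * (k - 1))       # residual

    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if ss_total == 0.0 or denom == 0.0:
        return ICCResult(np.nan, np.nan, np.nan, degenerate=True)
    icc = (msr - mse) / denom

    # McGraw & Wong F-based CI for ICC(A,1)
    alpha = 1.0 - confidence
    if mse == 0.0:
        return ICCResult(float(icc), float(icc), float(icc), degenerate=True)
    fj = msc / mse
    df_err = (n - 1) * (k - 1)
    term = n * (1.0 + (k - 1) * icc) - k * icc
    v_num = df_err * (k * icc * fj + term) ** 2
    v_den = (n - 1) * k**2 * icc**2 * fj**2 + term**2
    v = v_num / v_den
    f_up = stats.f.ppf(1.0 - alpha / 2.0, n - 1, v)
    f_low = stats.f.ppf(1.0 - alpha / 2.0, v, n - 1)
    ci_low = n * (msr - f_up * mse) / (
        f_up * (k * msc + (k * n - k - n) * mse) + n * msr
    )
    ci_high = n * (f_low * msr - mse) / (
        k * msc + (k * n - k - n) * mse + n * f_low * msr
    )
    return ICCResult(float(icc), float(ci_low), float(ci_high))


def friedman_test(matrix: np.ndarray) -> StatTestResult:
    """Tie-corrected Friedman rank test over an (eyes x algorithms) matrix.

    Within-row average ranks; the chi-square statistic uses the standard tie
    correction and degrades gracefully to (0, p=1) when every row is
    constant.  Handles k = 2 (where scipy's implementation refuses).
    """
    x = np.asarray(matrix, dtype=np.float64)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need at least 2 rows (eyes) and 2 columns (algorithms)")
    n, k = x.shape
    ranks = np.apply_along_axis(stats.rankdata, 1, x)
    col_sums = ranks.sum(axis=0)
    ss_dev = np.sum((col_sums - n * (k + 1) / 2.0) ** 2)
    denom = np.sum(ranks**2) - n * k * (k + 1) ** 2 / 4.0
    if denom == 0.0:
        return StatTestResult("Friedman", 0.0, 1.0)
    chi2 = (k - 1) * ss_dev / denom
    p = float(stats.chi2.sf(chi2, k - 1))
    return StatTestResult("Friedman", float(chi2), p)


def pairwise_posthoc(
    matrix: np.ndarray, names: Sequence[str] | None = None
) -> list[StatTestResult]:
    """Wilcoxon signed-rank test per algorithm pair, Holm-corrected as a family."""
    x = np.asarray(matrix, dtype=np.float64)
    n, k = x.shape
    if k < 2:
        raise ValueError("need at least 2 algorithms")
    names = list(names) if names is not None else [f"col{i}" for i in range(k)]
    raw: list[tuple[str, float, float]] = []
    for i, j in itertools.combinations(range(k), 2):
        d = x[:, j] - x[:, i]
        if np.all(d == 0.0):
            raw.append((f"{names[i]} vs {names[j]}", 0.0, 1.0))
            continue
        res = stats.wilcoxon(x[:, i], x[:, j], zero_method="wilcox")
        raw.append((f"{names[i]} vs {names[j]}", float(res.statistic), float(res.pvalue)))
    corrected = holm_bonferroni([p for _, _, p in raw])
    return [
        StatTestResult(name, statistic, p, p_c)
        for (name, statistic, p), p_c in zip(raw, corrected)
    ]


def mann_whitney(
    group_a: Sequence[float], group_b: Sequence[float], exact_cutoff: int = 8
) -> StatTestResult:
    """Two-sided Mann-Whitney-U: exact for small tie-free groups, else
    normal approximation with tie correction."""
    a = np.asarray(group_a, dtype=np.float64)
    b = np.asarray(group_b, dtype=np.float64)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    small = max(len(a), len(b)) <= exact_cutoff
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return StatTestResult("Mann-Whitney-U", float(res.statistic), float(res.pvalue))


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> StatTestResult:
    """Kruskal-Wallis H with tie correction, chi-square p-value."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=np.float64) for g in groups]
    if all(np.all(g == arrays[0][0]) for g in arrays):
        return StatTestResult("Kruskal-Wallis", 0.0, 1.0)
    res = stats.kruskal(*arrays)
    return StatTestResult("Kruskal-Wallis", float(res.statistic), float(res.pvalue))


def holm_bonferroni(pvals: Sequence[float]) -> list[float]:
    """Holm step-down corrected p-values, in the original order, capped at 1."""
    p = np.asarray(pvals, dtype=np.float64)
    if len(p) == 0:
        return []
    if np.any((p < 0.0) | (p > 1.0)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1].tolist()


def age_adjusted_regression(
    table: pd.DataFrame,
    dependent: str = "relative_difference",
    algorithms: Sequence[str] | None = None,
) -> RegressionResult:
    """OLS of relative differences on age plus 0/1 algorithm indicators.

    The indicator columns span the intercept, so no separate constant is
    included.  ``table`` needs columns ``dependent``, ``age``, ``algorithm``.
    Raises on a rank-deficient design, naming the collinear columns.
    """
    if algorithms is None:
        algorithms = sorted(table["algorithm"].unique())
    X = pd.DataFrame({"age": table["age"].to_numpy(dtype=float)})
    for algo in algorithms:
        X[f"algo_{algo}"] = (table["algorithm"] == algo).astype(float).to_numpy()
    y = table[dependent].to_numpy(dtype=float)
    if len(y) < X.shape[1] + 1:
        raise ValueError("not enough rows to span all predictors")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # identify columns whose removal restores full rank
        collinear = [
            c
            for c in X.columns
            if np.linalg.matrix_rank(X.drop(columns=c).to_numpy()) == rank
        ]
        raise ValueError(f"rank-deficient design; collinear columns: {collinear}")
    fit = sm.OLS(y, X).fit()
    return RegressionResult(fit.params, fit.pvalues, fit.conf_int())


def friedman_power_simulation(
    group_means: Sequence[float],
    group_sds: Sequence[float],
    n_eyes: int,
    reps: int = 10000,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Monte-Carlo power of the Friedman test for given per-algorithm normals.

    Each replicate draws ``n_eyes`` rows of independent normal values (one
    per algorithm) and counts rejections at ``alpha``.
    """
    means = np.asarray(group_means, dtype=np.float64)
    sds = np.asarray(group_sds, dtype=np.float64)
    if means.shape != sds.shape or means.ndim != 1 or len(means) < 2:
        raise ValueError("group_means and group_sds must be equal-length 1-D, k >= 2")
    if reps < 1 or n_eyes < 2:
        raise ValueError("reps >= 1 and n_eyes >= 2 required")
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(reps):
        data = rng.normal(means, sds, size=(n_eyes, len(means)))
        if friedman_test(data).p < alpha:
            rejections += 1
    return rejections / reps
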