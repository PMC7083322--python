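"""Agreement statistics: brute-force oracles, calibration, recovery."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from octarep.repeatability import (
    age_adjusted_regression,
    friedman_power_simulation,
    friedman_test,
    holm_bonferroni,
    icc_single,
    kruskal_wallis,
    mann_whitney,
    pairwise_posthoc,
    relative_difference,
    repeatability_coefficient,
)


# ---------------------------------------------------------------------------
# relative difference & RC

def test_relative_difference_examples():
    assert relative_difference(0.2, 0.2) == 0.0
    assert relative_difference(0.2, 0.1) == pytest.approx(0.1 / 0.15)
    assert relative_difference(0.0, 0.0) == 0.0
    rng = np.random.default_rng(0)
    for _ in range(20):
        a, b = rng.uniform(0.01, 1.0, 2)
        assert relative_difference(a, b) == relative_difference(b, a)


def test_rc_oracle_and_examples():
    assert repeatability_coefficient(np.array([[1.0, 1.0], [2.0, 2.0]])) == 0.0
    assert repeatability_coefficient(np.array([[0.0, 1.0]])) == pytest.approx(1.96)
    assert repeatability_coefficient(np.array([[0.0, 1.0]] * 4)) == pytest.approx(1.96)
    rng = np.random.default_rng(1)
    for _ in range(50):
        n = int(rng.integers(1, 30))
        pairs = rng.normal(0, 1, (n, 2))
        # independently coded oracle: plain loop over the printed formula
        acc = 0.0
        for m1, m2 in pairs:
            acc += (m2 - m1) ** 2
        oracle = 1.96 * math.sqrt(acc / n)
        assert repeatability_coefficient(pairs) == pytest.approx(oracle, abs=1e-10)
    with pytest.raises(ValueError):
        repeatability_coefficient(np.empty((0, 2)))


# ---------------------------------------------------------------------------
# ICC

def icc_anova_oracle(data: np.ndarray) -> float:
    """ICC(A,1) from an explicitly assembled two-way ANOVA table."""
    n, k = data.shape
    subj = data.mean(axis=1)
    meas = data.mean(axis=0)
    grand = data.mean()
    msr = k * ((subj - grand) ** 2).sum() / (n - 1)
    msc = n * ((meas - grand) ** 2).sum() / (k - 1)
    sse = 0.0
    for i in range(n):
        for j in range(k):
            sse += (data[i, j] - subj[i] - meas[j] + grand) ** 2
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


def test_icc_perfect_agreement():
    res = icc_single(np.array([[1.0, 1.0], [2.0, 2.0], [3.0, 3.0]]))
    assert res.icc == pytest.approx(1.0)


def test_icc_matches_anova_oracle_on_random_data():
    rng = np.random.default_rng(42)
    for _ in range(50):
        n = int(rng.integers(3, 40))
        data = rng.normal(0, 1, (n, 2)) + rng.normal(0, 1, (n, 1))
        res = icc_single(data)
        assert res.icc == pytest.approx(icc_anova_oracle(data), abs=1e-10)
        assert res.ci_low <= res.icc <= res.ci_high
        assert res.icc <= 1.0


def test_icc_matches_pingouin():
    pingouin = pytest.importorskip("pingouin")
    rng = np.random.default_rng(3)
    data = rng.normal(0, 1, (15, 2)) + rng.normal(0, 2, (15, 1))
    long = pd.DataFrame(
        {
            "subject": np.repeat(np.arange(15), 2),
            "rater": np.tile([0, 1], 15),
            "score": data.ravel(),
        }
    )
    pg = pingouin.intraclass_corr(long, targets="subject", raters="rater", ratings="score")
    row = pg[pg["Type"] == "ICC(A,1)"].iloc[0]
    res = icc_single(data)
    assert res.icc == pytest.approx(row["ICC"], abs=1e-6)
    # pingouin rounds the interval to 2 decimals
    assert res.ci_low == pytest.approx(row["CI95"][0], abs=6e-3)
    assert res.ci_high == pytest.approx(row["CI95"][1], abs=6e-3)


def test_icc_permuted_agreement_near_zero():
    rng = np.random.default_rng(8)
    first = rng.normal(0, 1, 40)
    data = np.column_stack([first, rng.permutation(first)])
    res = icc_single(data)
    assert abs(res.icc) < 0.5
    assert res.icc == pytest.approx(icc_anova_oracle(data), abs=1e-10)


def test_icc_recovers_variance_ratio():
    rng = np.random.default_rng(12)
    sigma_b, sigma_w = 2.0, 1.0
    truth = sigma_b**2 / (sigma_b**2 + sigma_w**2)
    n = 200
    iccs = []
    for _ in range(20):
        subj = rng.normal(0, sigma_b, (n, 1))
        data = subj + rng.normal(0, sigma_w, (n, 2))
        iccs.append(icc_single(data).icc)
    assert np.mean(iccs) == pytest.approx(truth, abs=0.03)


def test_icc_degenerate_constant_data():
    res = icc_single(np.full((5, 2), 3.0))
    assert res.degenerate and np.isnan(res.icc)


# ---------------------------------------------------------------------------
# Friedman

def test_friedman_trivial_and_strong():
    x = np.tile([1.0, 2.0, 3.0], (5, 1))
    x_identical = np.ones((5, 3))
    res = friedman_test(x_identical)
    assert res.statistic == 0.0 and res.p == 1.0
    # identical column order in every row, n=10, k=3: chi2 = 2n = 20
    res = friedman_test(np.tile([1.0, 2.0, 3.0], (10, 1)))
    assert res.statistic == pytest.approx(20.0)
    assert res.p < 0.01


def test_friedman_matches_scipy():
    rng = np.random.default_rng(5)
    for _ in range(10):
        x = rng.normal(0, 1, (12, 4))
        mine = friedman_test(x)
        ref = stats.friedmanchisquare(*(x[:, j] for j in range(4)))
        assert mine.statistic == pytest.approx(ref.statistic, abs=1e-10)
        assert mine.p == pytest.approx(ref.pvalue, abs=1e-12)


def test_friedman_permutation_null_4x3():
    """Chi-square p vs the exact within-row permutation null on a 4x3 matrix."""
    x = np.array(
        [[0.1, 0.5, 0.9], [0.2, 0.8, 0.4], [0.3, 0.6, 0.7], [0.15, 0.55, 0.95]]
    )
    obs = friedman_test(x).statistic
    perms = list(itertools.permutations(range(3)))
    count = total = 0
    for combo in itertools.product(perms, repeat=4):
        xm = np.vstack([x[i, list(pi)] for i, pi in enumerate(combo)])
        total += 1
        if friedman_test(xm).statistic >= obs - 1e-12:
            count += 1
    p_exact = count / total
    p_approx = friedman_test(x).p
    # the chi-square approximation is rough at n=4; both must agree on
    # order of magnitude and rejection at the 10% level
    assert p_exact == pytest.approx(p_approx, abs=0.05)
    assert (p_exact < 0.10) == (p_approx < 0.10)


def test_friedman_type_i_calibration():
    rng = np.random.default_rng(99)
    alpha = 0.05
    reps = 1000
    rejections = sum(
        friedman_test(rng.normal(0, 1, (12, 5))).p < alpha for _ in range(reps)
    )
    rate = rejections / reps
    se = math.sqrt(alpha * (1 - alpha) / reps)
    assert abs(rate - alpha) < 3 * se + 0.005


# ---------------------------------------------------------------------------
# post-hoc, Mann-Whitney, Kruskal-Wallis, Holm

def test_pairwise_posthoc_family():
    rng = np.random.default_rng(4)
    x = rng.normal(0, 1, (15, 7))
    results = pairwise_posthoc(x, names=list("ABCDEFG"))
    assert len(results) == 21                # C(7,2)
    for r in results:
        assert r.p_corrected >= r.p - 1e-15
        assert r.p_corrected <= 1.0
    same = np.column_stack([x[:, 0], x[:, 0]])
    res = pairwise_posthoc(same, names=["a", "b"])
    assert res[0].p == 1.0 and res[0].p_corrected == 1.0


def test_mann_whitney_exact_example():
    res = mann_whitney([1, 2, 3], [10, 11, 12])
    assert res.statistic == 0.0
    assert res.p == pytest.approx(0.1)       # 2/20 arrangements as extreme
    res = mann_whitney([1, 2, 3], [1, 2, 3])
    assert res.p == pytest.approx(1.0)


def test_mann_whitney_u_identity():
    rng = np.random.default_rng(6)
    a = rng.normal(0, 1, 12)
    b = rng.normal(0.5, 1, 9)
    ua = mann_whitney(a, b).statistic
    ub = mann_whitney(b, a).statistic
    assert ua + ub == pytest.approx(len(a) * len(b))


def test_kruskal_wallis_cases():
    assert kruskal_wallis([[1.0, 1.0], [1.0, 1.0]]).statistic == 0.0
    res = kruskal_wallis([[1, 2, 3, 4, 5], [10, 11, 12, 13, 14], [20, 21, 22, 23, 24]])
    assert res.p < 0.01
    rng = np.random.default_rng(7)
    a, b = rng.normal(0, 1, 20), rng.normal(1, 1, 20)
    kw = kruskal_wallis([a, b])
    mw = mann_whitney(a, b)
    assert (kw.p < 0.05) == (mw.p < 0.05)


def test_holm_bonferroni_oracle():
    assert holm_bonferroni([0.03]) == [0.03]
    assert holm_bonferroni([0.01, 0.04]) == pytest.approx([0.02, 0.04])
    assert holm_bonferroni([0.5, 0.5, 0.5]) == pytest.approx([1.0, 1.0, 1.0])
    rng = np.random.default_rng(11)
    for _ in range(50):
        m = int(rng.integers(1, 12))
        p = rng.uniform(0, 1, m)
        # independently coded step-down oracle
        order = np.argsort(p)
        corrected = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            val = min(1.0, (m - rank) * p[idx])
            running = max(running, val)
            corrected[idx] = running
        assert holm_bonferroni(p) == pytest.approx(corrected.tolist(), abs=1e-10)
    with pytest.raises(ValueError):
        holm_bonferroni([1.2])


# ---------------------------------------------------------------------------
# regression & power

def _regression_data(rng, n, beta_age, manual_effect):
    algos = ["Manual", "Huang", "Li", "Otsu", "Moments", "Mean", "Percentile"]
    algorithm = rng.choice(algos, n)
    age = rng.uniform(20, 75, n)
    y = beta_age * age + manual_effect * (algorithm == "Manual") + rng.normal(0, 0.1, n)
    return pd.DataFrame({"relative_difference": y, "age": age, "algorithm": algorithm})


def test_regression_recovers_zero_age_effect():
    rng = np.random.default_rng(21)
    table = _regression_data(rng, 500, beta_age=0.0, manual_effect=0.0)
    res = age_adjusted_regression(table)
    lo, hi = res.conf_int.loc["age"]
    assert lo <= 0.0 <= hi


def test_regression_recovers_manual_effect():
    rng = np.random.default_rng(22)
    table = _regression_data(rng, 500, beta_age=0.0, manual_effect=0.6)
    res = age_adjusted_regression(table)
    others = [k for k in res.params.index if k.startswith("algo_") and k != "algo_Manual"]
    assert res.params["algo_Manual"] - np.mean([res.params[k] for k in others]) == pytest.approx(
        0.6, abs=0.05
    )
    assert res.pvalues["algo_Manual"] < 1e-4


def test_regression_rank_deficiency_names_columns():
    rng = np.random.default_rng(23)
    table = _regression_data(rng, 100, 0.0, 0.0)
    table["age"] = 1.0                       # constant age collides with indicators
    with pytest.raises(ValueError, match="collinear"):
        age_adjusted_regression(table)


def test_friedman_power_null_and_strong_effect():
    sds = [1.0] * 4
    p_null = friedman_power_simulation([0.0] * 4, sds, n_eyes=8, reps=400, seed=1)
    assert abs(p_null - 0.05) < 3 * math.sqrt(0.05 * 0.95 / 400) + 0.01
    p_strong = friedman_power_simulation([0.0, 5.0, 10.0, 15.0], [0.1] * 4,
                                         n_eyes=6, reps=200, seed=2)
    assert p_strong > 0.99


def test_friedman_power_monotone_in_n():
    means = [0.0, 0.8, 0.0, 0.8]
    sds = [1.0] * 4
    powers = [
        friedman_power_simulation(means, sds, n_eyes=n, reps=300, seed=3)
        for n in (4, 6, 10)
    ]
    assert powers[0] <= powers[1] <= powers[2]
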