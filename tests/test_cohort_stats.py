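"""Group-level inference: rank-sum, categorical tests, adjusted regression."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from wristt1 import (adjusted_group_effect, categorical_test, contrast_table,
                     cts_subgroup_contrast, default_t1_prior, grade_correlation,
                     wilcoxon_rank_sum)


# -- independent enumeration oracle for the rank-sum test --------------------

def ranksum_p_enumeration(x, y):
    """Two-sided p by full enumeration of rank assignments (no ties)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    m, n = x.size, y.size
    u_obs = ranks[:m].sum() - m * (m + 1) / 2
    us = []
    for comb in itertools.combinations(range(m + n), m):
        us.append(ranks[list(comb)].sum() - m * (m + 1) / 2)
    us = np.asarray(us)
    lo, hi = min(u_obs, m * n - u_obs), max(u_obs, m * n - u_obs)
    return min(1.0, ((us <= lo).sum() + (us >= hi).sum()) / us.size)


def test_ranksum_separated_triplets():
    # 2 of the 20 equally likely rank splits are as extreme
    assert wilcoxon_rank_sum([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)
    assert wilcoxon_rank_sum([1, 2, 3], [4, 5, 6]) == pytest.approx(
        ranksum_p_enumeration([1, 2, 3], [4, 5, 6]))


def test_ranksum_identical_samples_near_one(rng):
    x = rng.normal(size=20)
    assert wilcoxon_rank_sum(x, x) >= 0.99


def test_ranksum_exact_matches_enumeration(rng):
    for _ in range(30):
        x = rng.normal(size=5)
        y = rng.normal(size=6)
        assert wilcoxon_rank_sum(x, y) == pytest.approx(
            ranksum_p_enumeration(x, y), abs=1e-12)


def test_ranksum_approximation_close_to_exact(rng):
    """Normal approximation vs enumeration at n = 6+6 over random datasets."""
    worst = 0.0
    for _ in range(200):
        x = rng.normal(size=6)
        y = rng.normal(size=6) + rng.normal() * 0.5
        exact = ranksum_p_enumeration(x, y)
        approx = float(stats.mannwhitneyu(x, y, alternative="two-sided",
                                          method="asymptotic",
                                          use_continuity=True).pvalue)
        worst = max(worst, abs(exact - approx))
    assert worst < 0.03


def test_ranksum_monotone_transform_invariance(rng):
    x = rng.normal(size=15)
    y = rng.normal(size=20) + 0.8
    p0 = wilcoxon_rank_sum(x, y)
    assert wilcoxon_rank_sum(np.exp(x), np.exp(y)) == pytest.approx(p0)
    assert wilcoxon_rank_sum(x ** 3, y ** 3) == pytest.approx(p0)


def test_ranksum_empty_sample_rejected():
    with pytest.raises(ValueError):
        wilcoxon_rank_sum([], [1.0])


def fisher_p_hypergeom(table):
    """Two-sided Fisher p by hypergeometric enumeration."""
    a, b = table[0]
    c, d = table[1]
    row1, col1, n = a + b, a + c, a + b + c + d
    rv = stats.hypergeom(n, col1, row1)
    p_obs = rv.pmf(a)
    return sum(rv.pmf(k) for k in range(max(0, row1 + col1 - n), min(row1, col1) + 1)
               if rv.pmf(k) <= p_obs + 1e-12)


@pytest.mark.parametrize("table,check", [
    ([[10, 0], [0, 10]], lambda p: p < 0.001),
    ([[5, 5], [5, 5]], lambda p: p == pytest.approx(1.0)),
    ([[3, 1], [1, 3]], lambda p: p == pytest.approx(0.485714, abs=1e-4)),
])
def test_categorical_small_tables(table, check):
    assert check(categorical_test(table))


def test_categorical_matches_hypergeometric_oracle(rng):
    for _ in range(20):
        t = rng.integers(0, 5, size=(2, 2))
        if t.sum() == 0:
            continue
        assert categorical_test(t) == pytest.approx(fisher_p_hypergeom(t), abs=1e-9)


def test_categorical_large_table_uses_chi2():
    t = [[30, 20], [15, 40]]
    want = stats.chi2_contingency(np.asarray(t), correction=True)[1]
    assert categorical_test(t) == pytest.approx(want)


def test_categorical_all_zero_rejected():
    with pytest.raises(ValueError):
        categorical_test([[0, 0], [0, 0]])


def test_adjusted_effect_exact_linear_recovery(rng):
    n = 40
    group = np.r_[np.ones(n // 2), np.zeros(n // 2)]
    age = rng.uniform(30, 80, size=n)
    sex = rng.integers(0, 2, size=n).astype(float)
    t1 = 1000.0 - 150.0 * group  # noise-free group effect only
    p, params = adjusted_group_effect(t1, group, age, sex)
    assert params["group"] == pytest.approx(-150.0, abs=1e-8)
    assert p < 1e-12


def test_adjusted_effect_matches_normal_equations(rng):
    """OLS coefficients vs an explicit normal-equations solve."""
    n = 10
    group = np.r_[np.ones(5), np.zeros(5)]
    age = rng.uniform(30, 80, size=n)
    sex = np.array([1, 0, 1, 0, 1, 0, 1, 0, 1, 0], dtype=float)
    t1 = rng.normal(1000, 100, size=n)
    _, params = adjusted_group_effect(t1, group, age, sex)
    X = np.column_stack([np.ones(n), group, age, sex])
    beta = np.linalg.solve(X.T @ X, X.T @ t1)
    assert np.allclose(params.to_numpy(), beta, atol=1e-9)


def test_adjusted_effect_requires_both_groups(rng):
    n = 12
    with pytest.raises(ValueError):
        adjusted_group_effect(rng.normal(size=n), np.ones(n),
                              rng.uniform(30, 80, n), np.zeros(n))


def test_adjusted_effect_rejects_collinearity(rng):
    n = 12
    group = np.r_[np.ones(6), np.zeros(6)]
    sex = group.copy()           # sex identical to group -> age ok, sex collinear?
    age = group * 10 + 30        # age perfectly determined by group
    with pytest.raises(ValueError, match="collinear"):
        adjusted_group_effect(rng.normal(size=n), group, age, sex)


def test_grade_correlation_bands(rng):
    x = np.arange(10, dtype=float)
    strong = grade_correlation(x, 2 * x)
    assert strong.r == pytest.approx(1.0) and strong.grade == "strong"
    neg = grade_correlation(x, -2 * x)
    assert neg.r == pytest.approx(-1.0) and neg.grade == "strong"  # graded on |r|
    # build data with a prescribed sample correlation via Gram-Schmidt
    for target, want in [(0.45, "moderate"), (-0.25, "weak"), (0.31, "moderate")]:
        z = rng.normal(size=50)
        e = rng.normal(size=50)
        e -= e.mean() + 0  # center
        z = (z - z.mean()) / z.std()
        e = e - (e @ z) / (z @ z) * z
        e /= np.linalg.norm(e)
        y = abs(target) * z / np.linalg.norm(z) + np.sqrt(1 - target ** 2) * e
        y = np.sign(target) * y
        g = grade_correlation(z, y)
        assert g.r == pytest.approx(target, abs=1e-10)
        assert g.grade == want


def test_grade_correlation_zero_variance_rejected():
    with pytest.raises(ValueError):
        grade_correlation(np.ones(5), np.arange(5.0))


def test_cts_subgroup_medians_match_generator(prior):
    """Monte-Carlo: CTS-stratified SCF medians center on 885 / 1041 ms."""
    rng = np.random.default_rng(31)
    e_cts = prior.lookup("SCF", "patient", True)
    e_no = prior.lookup("SCF", "patient", False)
    med_cts, med_no = [], []
    for _ in range(500):
        med_cts.append(np.median(e_cts.sample(rng, size=16)))
        med_no.append(np.median(e_no.sample(rng, size=20)))
    assert np.median(med_cts) == pytest.approx(885, rel=0.03)
    assert np.median(med_no) == pytest.approx(1041, rel=0.03)


def test_cts_subgroup_contrast_table():
    df = pd.DataFrame({
        "group": ["patient"] * 4 + ["control"] * 2,
        "cts": [True, True, False, False, False, False],
        "age_years": [70] * 6, "sex": ["male"] * 6,
        "t1_SCF": [880.0, 880.0, 1040.0, 1040.0, 1150.0, 1170.0],
    })
    out = cts_subgroup_contrast(df, structures=("SCF",))
    assert out.loc["SCF", "cts_median"] == 880.0
    assert out.loc["SCF", "no_cts_median"] == 1040.0
    assert 0 <= out.loc["SCF", "p"] <= 1

    only_cts = df[df["cts"] | (df["group"] == "control")]
    with pytest.raises(ValueError):
        cts_subgroup_contrast(only_cts, structures=("SCF",))


def test_contrast_table_drops_invalid_and_reports_n(rng):
    n = 30
    df = pd.DataFrame({
        "group": ["patient"] * 12 + ["control"] * 18,
        "cts": [False] * 30,
        "age_years": rng.uniform(30, 85, n),
        "sex": rng.choice(["male", "female"], n),
        "t1_TCL": np.r_[rng.normal(830, 100, 12), rng.normal(990, 100, 18)],
    })
    df.loc[0, "t1_TCL"] = np.nan  # one invalid fit
    out = contrast_table(df, structures=("TCL",))
    assert out.loc["TCL", "n_patient"] == 11
    assert out.loc["TCL", "n_control"] == 18
    assert 0 <= out.loc["TCL", "p_raw"] <= 1
    assert 0 <= out.loc["TCL", "p_adjusted"] <= 1
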