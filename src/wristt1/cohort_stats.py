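"""Group-level inference on per-subject T1 values.

Implements the comparison battery used for a two-group (patient vs control)
T1 study: Wilcoxon rank-sum contrasts per structure, chi-square / Fisher
tests for categorical variables, an age- and sex-adjusted linear regression
per structure (T1 as the dependent variable, group as the exposure), Pearson
correlation with strength grading, and the CTS-stratified patient subgroup
contrast. No multiple-testing correction is applied across structures;
p values are reported as-is.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .tissues import REPORTED_STRUCTURES

#: Pearson |r| strength bands: > 0.5 strong, 0.3–0.5 moderate, < 0.3 weak.
CORR_STRONG = 0.5
CORR_MODERATE = 0.3


@dataclass(frozen=True)
class CorrelationGrade:
    r: float
    p: float
    grade: str  # "strong" | "moderate" | "weak"


@dataclass(frozen=True)
class GroupContrast:
    """One structure's two-group comparison (medians, IQRs, raw & adjusted p)."""

    structure: str
    median_a: float
    iqr_a: tuple[float, float]
    median_b: float
    iqr_b: tuple[float, float]
    p_raw: float
    p_adjusted: float | None
    n_a: int
    n_b: int


def wilcoxon_rank_sum(x, y) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p value.

    Exact null enumeration when the pooled sample is small (<= 12) and
    tie-free; otherwise the tie-corrected normal approximation with
    continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (pooled.size <= 12 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.pvalue)


def categorical_test(table) -> float:
    """2x2 association p value: Fisher's exact if any expected cell < 5, else
    chi-square with continuity correction."""
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2) or np.any(table < 0) or np.any(table != np.floor(table)):
        raise ValueError("table must be a 2x2 array of non-negative integers")
    if table.sum() == 0:
        raise ValueError("all-zero contingency table")
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    if np.any(expected < 5):
        return float(stats.fisher_exact(table.astype(int))[1])
    return float(stats.chi2_contingency(table, correction=True)[1])


def adjusted_group_effect(t1, group, age, sex) -> tuple[float, pd.Series]:
    """Age/sex-adjusted group effect on T1 via ordinary least squares.

    Fits ``T1 = b0 + b1*group + b2*age + b3*sex`` (group: 1 = patient,
    sex: 1 = male) and returns the two-sided p value on the group
    coefficient together with the full coefficient series.
    """
    t1 = np.asarray(t1, dtype=float)
    g = _binary(group, ("patient", 1), name="group")
    s = _binary(sex, ("male", 1), name="sex")
    age = np.asarray(age, dtype=float)
    if not (0 < g.sum() < g.size):
        raise ValueError("both groups must be present")
    X = np.column_stack([g, age, s])
    if t1.size < X.shape[1] + 1 + 4:
        raise ValueError("need at least 4 more subjects than parameters")
    X = sm.add_constant(X)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("collinear design matrix: group/age/sex are linearly dependent")
    fit = sm.OLS(t1, X).fit()
    params = pd.Series(fit.params, index=["const", "group", "age", "sex"])
    return float(fit.pvalues[1]), params


def amyloid_status_logit(t1, group, age, sex) -> tuple[float, pd.Series]:
    """Alternative framing: logistic regression of disease status on T1,
    adjusted for age and sex; returns the p value on the T1 coefficient."""
    g = _binary(group, ("patient", 1), name="group")
    s = _binary(sex, ("male", 1), name="sex")
    X = sm.add_constant(np.column_stack([np.asarray(t1, float),
                                         np.asarray(age, float), s]))
    fit = sm.Logit(g, X).fit(disp=0)
    params = pd.Series(fit.params, index=["const", "t1", "age", "sex"])
    return float(fit.pvalues[1]), params


def grade_correlation(x, y) -> CorrelationGrade:
    """Pearson correlation with strength grading on |r|."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance input")
    r, p = stats.pearsonr(x, y)
    a = abs(r)
    grade = "strong" if a > CORR_STRONG else ("moderate" if a >= CORR_MODERATE else "weak")
    return CorrelationGrade(r=float(r), p=float(p), grade=grade)


def _median_iqr(v: np.ndarray) -> tuple[float, tuple[float, float]]:
    return float(np.median(v)), (float(np.percentile(v, 25)), float(np.percentile(v, 75)))


def group_contrast(structure: str, values_a, values_b,
                   covariates: pd.DataFrame | None = None) -> GroupContrast:
    """Median (IQR) per arm plus rank-sum p; adjusted p when covariates given.

    ``covariates`` must then hold columns group/age/sex aligned with the
    concatenation of the two arms (arm a first).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError(f"empty arm in contrast for {structure}")
    med_a, iqr_a = _median_iqr(a)
    med_b, iqr_b = _median_iqr(b)
    p_raw = wilcoxon_rank_sum(a, b)
    p_adj = None
    if covariates is not None:
        p_adj, _ = adjusted_group_effect(np.concatenate([a, b]),
                                         covariates["group"], covariates["age"],
                                         covariates["sex"])
    return GroupContrast(structure=structure, median_a=med_a, iqr_a=iqr_a,
                         median_b=med_b, iqr_b=iqr_b, p_raw=p_raw,
                         p_adjusted=p_adj, n_a=int(a.size), n_b=int(b.size))


def contrast_table(df: pd.DataFrame, structures=REPORTED_STRUCTURES,
                   value_prefix: str = "t1_") -> pd.DataFrame:
    """Per-structure patient-vs-control table: median (IQR) per group, raw
    Wilcoxon p and age/sex-adjusted p.

    ``df`` needs columns ``group`` ("patient"/"control"), ``age_years``,
    ``sex`` and one ``<value_prefix><structure>`` column per structure;
    rows with NaN values (invalid fits) are dropped per structure and the
    retained n reported.
    """
    rows = []
    for structure in structures:
        col = f"{value_prefix}{structure}"
        sub = df[["group", "age_years", "sex", col]].dropna(subset=[col])
        pat = sub.loc[sub["group"] == "patient", col].to_numpy()
        con = sub.loc[sub["group"] == "control", col].to_numpy()
        cov = pd.DataFrame({
            "group": np.r_[["patient"] * pat.size, ["control"] * con.size],
            "age": np.r_[sub.loc[sub["group"] == "patient", "age_years"],
                         sub.loc[sub["group"] == "control", "age_years"]],
            "sex": np.r_[sub.loc[sub["group"] == "patient", "sex"],
                         sub.loc[sub["group"] == "control", "sex"]],
        })
        c = group_contrast(structure, pat, con, covariates=cov)
        rows.append({"structure": structure,
                     "patient_median": c.median_a, "patient_q1": c.iqr_a[0],
                     "patient_q3": c.iqr_a[1],
                     "control_median": c.median_b, "control_q1": c.iqr_b[0],
                     "control_q3": c.iqr_b[1],
                     "p_raw": c.p_raw, "p_adjusted": c.p_adjusted,
                     "n_patient": c.n_a, "n_control": c.n_b})
    return pd.DataFrame(rows).set_index("structure")


def cts_subgroup_contrast(df: pd.DataFrame, structures=REPORTED_STRUCTURES,
                          value_prefix: str = "t1_") -> pd.DataFrame:
    """Within-patient contrast: CTS vs asymptomatic, median (IQR) + Wilcoxon p."""
    pat = df[df["group"] == "patient"]
    with_cts = pat[pat["cts"].astype(bool)]
    without = pat[~pat["cts"].astype(bool)]
    if len(with_cts) == 0 or len(without) == 0:
        raise ValueError("both CTS subgroups must be non-empty")
    rows = []
    for structure in structures:
        col = f"{value_prefix}{structure}"
        a = with_cts[col].dropna().to_numpy()
        b = without[col].dropna().to_numpy()
        c = group_contrast(structure, a, b)
        rows.append({"structure": structure,
                     "cts_median": c.median_a, "cts_q1": c.iqr_a[0],
                     "cts_q3": c.iqr_a[1],
                     "no_cts_median": c.median_b, "no_cts_q1": c.iqr_b[0],
                     "no_cts_q3": c.iqr_b[1],
                     "p": c.p_raw, "n_cts": c.n_a, "n_no_cts": c.n_b})
    return pd.DataFrame(rows).set_index("structure")


def _binary(values, positive: tuple[str, int], name: str = "variable") -> np.ndarray:
    """Map a string/bool/0-1 vector to 0/1 with ``positive`` mapped to 1."""
    arr = np.asarray(values)
    if arr.dtype.kind in "biufc":
        out = arr.astype(float)
        if not np.isin(out, (0.0, 1.0)).all():
            raise ValueError(f"{name} must be binary")
        return out
    return (arr == positive[0]).astype(float)
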