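"""ROC analysis of per-structure T1 for discriminating patients from controls.

Orientation is fixed to lower-T1-indicates-disease for every structure (the
observed direction of effect); the sign is deliberately not auto-detected,
which would optimistically bias the AUC. The AUC is computed through the
Mann-Whitney rank identity (ties count one half); its confidence interval by
the DeLong structural-components variance estimator by default, or by a
stratified bootstrap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats


class RocError(ValueError):
    """Degenerate ROC input (a class missing, bad labels)."""


@dataclass(frozen=True)
class OperatingPoint:
    """Counts and rates at one decision threshold (positive = score < threshold)."""

    threshold: float
    tp: int
    fn: int
    tn: int
    fp: int

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp)

    @property
    def sensitivity_pct(self) -> int:
        return round(100 * self.sensitivity)

    @property
    def specificity_pct(self) -> int:
        return round(100 * self.specificity)


@dataclass(frozen=True)
class RocResult:
    """Empirical ROC curve with AUC and 95% CI (lower-score-positive)."""

    auc: float
    ci95: tuple[float, float]
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    direction: str = "lower_is_positive"
    ci_method: str = "delong"
    degenerate_ci: bool = False


def _split(scores, labels, positive_label: str = "patient"):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == positive_label]
    neg = scores[labels != positive_label]
    if pos.size == 0 or neg.size == 0:
        raise RocError("both classes must be present")
    return pos, neg


def auc_mann_whitney(pos, neg) -> float:
    """P(pos < neg) + 0.5 P(pos = neg) via midranks (lower score = diseased)."""
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    # rank-sum identity on -scores orientation: count neg above pos
    r_pos = ranks[: pos.size].sum()
    u = r_pos - pos.size * (pos.size + 1) / 2          # pairs with pos > neg (+ half ties)
    return 1.0 - u / (pos.size * neg.size)


def roc(scores, labels, positive_label: str = "patient",
        ci_method: str = "delong", seed: int | None = 0,
        n_boot: int = 2000) -> RocResult:
    """Empirical ROC with lower-score-positive orientation.

    ``scores`` are T1 values (ms); ``labels`` the class strings. The curve is
    swept over thresholds from below the minimum to above the maximum score;
    a subject is called positive when its score is strictly below the
    threshold, so the curve starts at (0, 0) and ends at (1, 1).
    """
    pos, neg = _split(scores, labels, positive_label)
    auc = auc_mann_whitney(pos, neg)
    thr = np.concatenate([[-np.inf], np.unique(np.concatenate([pos, neg])),
                          [np.inf]])
    # positive call: score < t; sweep upward so fpr/tpr are non-decreasing
    tpr = np.array([(pos < t).mean() for t in thr[1:]])
    fpr = np.array([(neg < t).mean() for t in thr[1:]])
    tpr = np.concatenate([[0.0], tpr])
    fpr = np.concatenate([[0.0], fpr])
    ci, degenerate = auc_ci(scores, labels, method=ci_method, seed=seed,
                            n_boot=n_boot, positive_label=positive_label,
                            _return_flag=True)
    return RocResult(auc=float(auc), ci95=ci, fpr=fpr, tpr=tpr,
                     thresholds=thr, ci_method=ci_method,
                     degenerate_ci=degenerate)


def _delong_variance(pos, neg) -> float:
    """DeLong variance of the (lower-positive) AUC via structural components."""
    m, n = pos.size, neg.size
    # orient so larger = more diseased, matching the standard derivation
    x = -np.asarray(pos, float)   # diseased
    y = -np.asarray(neg, float)   # healthy
    all_ranks = stats.rankdata(np.concatenate([x, y]))
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    auc = (all_ranks[:m].sum() - m * (m + 1) / 2) / (m * n)
    v10 = (all_ranks[:m] - rx) / n          # per-diseased placement values
    v01 = 1.0 - (all_ranks[m:] - ry) / m    # per-healthy placement values
    s10 = np.var(v10, ddof=1) if m > 1 else 0.0
    s01 = np.var(v01, ddof=1) if n > 1 else 0.0
    del auc
    return s10 / m + s01 / n


def auc_ci(scores, labels, method: str = "delong", seed: int | None = 0,
           n_boot: int = 2000, positive_label: str = "patient",
           _return_flag: bool = False):
    """95% CI for the lower-positive AUC; DeLong (default) or stratified
    percentile bootstrap. Degenerate cases (zero estimated variance at
    AUC 0 or 1) get a floor variance of 1/(4 m n) and are flagged."""
    pos, neg = _split(scores, labels, positive_label)
    auc = auc_mann_whitney(pos, neg)
    degenerate = False
    if method == "delong":
        var = _delong_variance(pos, neg)
        if var == 0.0:
            var = 1.0 / (4.0 * pos.size * neg.size)
            degenerate = True
        half = stats.norm.ppf(0.975) * np.sqrt(var)
        ci = (float(max(0.0, auc - half)), float(min(1.0, auc + half)))
    elif method == "bootstrap":
        rng = np.random.default_rng(seed)
        reps = np.empty(n_boot)
        for b in range(n_boot):
            p = rng.choice(pos, size=pos.size, replace=True)
            c = rng.choice(neg, size=neg.size, replace=True)
            reps[b] = auc_mann_whitney(p, c)
        ci = (float(np.percentile(reps, 2.5)), float(np.percentile(reps, 97.5)))
        if ci[0] == ci[1]:
            degenerate = True
    else:
        raise ValueError(f"unknown CI method {method!r}")
    return (ci, degenerate) if _return_flag else ci


def operating_point(scores, labels, threshold: float,
                    positive_label: str = "patient") -> OperatingPoint:
    """Confusion counts at a threshold; positive call = score strictly below."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    pos, neg = _split(scores, labels, positive_label)
    tp = int((pos < threshold).sum())
    fn = pos.size - tp
    fp = int((neg < threshold).sum())
    tn = neg.size - fp
    return OperatingPoint(threshold=float(threshold), tp=tp, fn=fn, tn=tn, fp=fp)


def youden_threshold(scores, labels, positive_label: str = "patient") -> float:
    """Threshold maximizing sensitivity + specificity - 1 (lower-positive)."""
    pos, neg = _split(scores, labels, positive_label)
    candidates = np.unique(np.concatenate([pos, neg]))
    # midpoints above each score so 'strictly below' includes it
    eps = np.diff(candidates, append=candidates[-1] + 1.0) / 2
    best_t, best_j = candidates[0], -np.inf
    for t in np.concatenate([candidates + eps, [candidates[0] - 1.0]]):
        op = operating_point(np.concatenate([pos, neg]),
                             np.array([positive_label] * pos.size + ["other"] * neg.size),
                             t, positive_label)
        j = op.sensitivity + op.specificity - 1.0
        if j > best_j:
            best_j, best_t = j, t
    return float(best_t)
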