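"""Two-reader reliability: intraclass correlation and Bland-Altman.

The ICC variant is ICC(2,1) — two-way random effects, absolute agreement,
single measure — the conservative standard for two fixed readers re-reading
the same scans; its 95% CI comes from the F-distribution formulas. Reliability
bands: < 0.5 poor, 0.5-0.75 moderate, 0.75-0.9 good, > 0.9 excellent.

A second reader is simulated by randomly perturbing the ROI masks
(morphological erosion/dilation or translation) and re-running the signal
aggregation: in this kind of study, inter-reader disagreement arises from
contouring, not from the images themselves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import ndimage

from .phantom import PhantomStudy
from .roi import EmptyROIError, SignalTable, roi_mean
from .tissues import GCW, REPORTED_STRUCTURES, TissueClass


@dataclass(frozen=True)
class AgreementResult:
    icc: float
    icc_ci95: tuple[float, float]
    reliability_band: str
    bias: float
    loa95: tuple[float, float]
    n: int


def reliability_band(icc: float) -> str:
    if icc < 0.5:
        return "poor"
    if icc < 0.75:
        return "moderate"
    if icc < 0.9:
        return "good"
    return "excellent"


def icc_two_reader(values) -> tuple[float, tuple[float, float]]:
    """ICC(2,1) with F-based 95% CI for an (n_subjects, 2) reading matrix."""
    v = np.asarray(values, dtype=float)
    if v.ndim != 2 or v.shape[1] != 2:
        raise ValueError("values must be (n_subjects, 2)")
    if v.shape[0] < 5:
        raise ValueError("need at least 5 subjects")
    if np.isnan(v).any():
        raise ValueError("missing readings are not allowed (no imputation)")
    n = v.shape[0]
    df = pd.DataFrame({
        "subject": np.repeat(np.arange(n), 2),
        "reader": np.tile([0, 1], n),
        "value": v.reshape(-1),
    })
    res = pg.intraclass_corr(data=df, targets="subject", raters="reader",
                             ratings="value").set_index("Type")
    # two-way random, absolute agreement, single measure; label varies by version
    label = "ICC(A,1)" if "ICC(A,1)" in res.index else "ICC2"
    row = res.loc[label]
    ci_col = "CI95" if "CI95" in res.columns else "CI95%"
    return float(row["ICC"]), (float(row[ci_col][0]), float(row[ci_col][1]))


def bland_altman(values) -> tuple[float, tuple[float, float]]:
    """Mean bias (reader1 - reader2) and 95% limits of agreement
    (bias +/- 1.96 * sample SD of the differences)."""
    v = np.asarray(values, dtype=float)
    if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 2:
        raise ValueError("values must be (n_subjects >= 2, 2)")
    d = v[:, 0] - v[:, 1]
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return bias, (bias - 1.96 * sd, bias + 1.96 * sd)


def agreement_summary(values) -> AgreementResult:
    """ICC(2,1), reliability band, and Bland-Altman bias/limits in one pass."""
    icc, ci = icc_two_reader(values)
    bias, loa = bland_altman(values)
    return AgreementResult(icc=icc, icc_ci95=ci, reliability_band=reliability_band(icc),
                           bias=bias, loa95=loa, n=int(np.asarray(values).shape[0]))


def _jitter_mask(mask: np.ndarray, jitter: int, rng: np.random.Generator) -> np.ndarray:
    """Randomly erode, dilate, or translate a binary mask by up to ``jitter`` px."""
    if jitter == 0:
        return mask
    op = rng.integers(0, 3)
    amount = int(rng.integers(1, jitter + 1))
    if op == 0:
        out = ndimage.binary_erosion(mask, iterations=amount)
    elif op == 1:
        out = ndimage.binary_dilation(mask, iterations=amount)
    else:
        shift = rng.integers(-amount, amount + 1, size=2)
        out = ndimage.shift(mask.astype(float), shift, order=0) > 0.5
    return out


def reader_perturbation(study: PhantomStudy, mask_jitter: int,
                        rng: np.random.Generator | int | None = None) -> SignalTable:
    """Simulate a second reader: perturb each structure's per-level mask and
    re-aggregate the signals. ``mask_jitter = 0`` reproduces reader 1 exactly.
    """
    if mask_jitter < 0:
        raise ValueError("mask_jitter must be >= 0")
    rng = np.random.default_rng(rng)
    nl, na = study.images.shape[:2]
    angles = list(study.protocol.flip_angles_deg)
    rows, audit = {}, {}
    for structure in REPORTED_STRUCTURES:
        base = (study.masks > 0) if structure == GCW \
            else (study.masks == TissueClass[structure])
        per_level = np.empty((nl, na))
        for lv in range(nl):
            m2 = _jitter_mask(base[lv], mask_jitter, rng)
            if not m2.any():
                raise EmptyROIError(
                    f"jitter destroyed structure {structure} at level {lv}")
            for ia in range(na):
                per_level[lv, ia] = roi_mean(study.images[lv, ia], m2,
                                             structure=structure, level=lv)
            audit[(structure, lv)] = per_level[lv].tolist()
        rows[structure] = per_level.mean(axis=0)
    means = pd.DataFrame.from_dict(rows, orient="index", columns=angles)
    means = means.loc[list(REPORTED_STRUCTURES)]
    audit_df = pd.DataFrame.from_dict(audit, orient="index", columns=angles)
    audit_df.index = pd.MultiIndex.from_tuples(audit_df.index,
                                               names=["structure", "level"])
    return SignalTable(means=means, per_level=audit_df)
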