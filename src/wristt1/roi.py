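"""Per-structure signal aggregation across flip angles and slice levels.

For every structure the ROI mean signal is computed per slice level, and the
per-level means are then averaged (unweighted) across levels — the averaging
order is per-level-mean-then-across-levels, *not* a pooled-pixel mean, so a
level with a small ROI counts as much as one with a large ROI. A pooled-pixel
alternative is available behind the ``pooled`` flag for sensitivity analysis.

GCW — the global wrist contour — is the union of the five named structures
plus the OTHER interior, aggregated the same way.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .phantom import PhantomStudy
from .tissues import GCW, NAMED_STRUCTURES, REPORTED_STRUCTURES, TissueClass


class EmptyROIError(ValueError):
    """A structure's mask is empty at some level."""


def roi_mean(image: np.ndarray, mask: np.ndarray, *, structure: str = "?",
             level: int | str = "?") -> float:
    """Arithmetic mean of the pixel values under a binary mask."""
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if image.shape != mask.shape:
        raise ValueError(f"image {image.shape} and mask {mask.shape} shapes differ")
    if not mask.any():
        raise EmptyROIError(f"empty ROI for structure {structure} at level {level}")
    return float(image[mask].mean())


@dataclass
class SignalTable:
    """Aggregated per-structure signals.

    Attributes
    ----------
    means : pandas.DataFrame
        One row per structure (including GCW), one column per flip angle
        (degrees): the across-level average of per-level ROI means.
    per_level : pandas.DataFrame
        Audit table of raw per-level ROI means, indexed by (structure, level).
    """

    means: pd.DataFrame
    per_level: pd.DataFrame


def _structure_mask(masks: np.ndarray, structure: str) -> np.ndarray:
    """Boolean per-level masks (n_levels, H, W) for a structure or GCW."""
    if structure == GCW:
        return masks > 0  # five structures + OTHER interior
    return masks == TissueClass[structure]


def aggregate_structure(study: PhantomStudy, structure: str,
                        pooled: bool = False) -> np.ndarray:
    """Per-flip-angle aggregated mean signal for one structure (or GCW).

    Default: mean over levels of the per-level ROI means. ``pooled=True``
    instead pools all masked pixels across levels (area-weighted).
    """
    sel = _structure_mask(study.masks, structure)
    nl, na = study.images.shape[:2]
    out = np.empty(na)
    for ia in range(na):
        if pooled:
            pix = [study.images[lv, ia][sel[lv]] for lv in range(nl)]
            if any(p.size == 0 for p in pix):
                raise EmptyROIError(f"empty ROI for structure {structure}")
            out[ia] = float(np.concatenate(pix).mean())
        else:
            out[ia] = np.mean([roi_mean(study.images[lv, ia], sel[lv],
                                        structure=structure, level=lv)
                               for lv in range(nl)])
    return out


def gcw_row(study: PhantomStudy, pooled: bool = False) -> np.ndarray:
    """Aggregated signal of the global wrist contour (union region)."""
    return aggregate_structure(study, GCW, pooled=pooled)


def signal_table(study: PhantomStudy, pooled: bool = False) -> SignalTable:
    """Build the full six-row signal table (five structures + GCW)."""
    angles = list(study.protocol.flip_angles_deg)
    nl = study.protocol.n_levels
    rows, audit = {}, {}
    for structure in REPORTED_STRUCTURES:
        rows[structure] = aggregate_structure(study, structure, pooled=pooled)
        sel = _structure_mask(study.masks, structure)
        for lv in range(nl):
            audit[(structure, lv)] = [roi_mean(study.images[lv, ia], sel[lv],
                                               structure=structure, level=lv)
                                      for ia in range(len(angles))]
    means = pd.DataFrame.from_dict(rows, orient="index", columns=angles)
    means = means.loc[list(REPORTED_STRUCTURES)]
    per_level = pd.DataFrame.from_dict(audit, orient="index", columns=angles)
    per_level.index = pd.MultiIndex.from_tuples(per_level.index,
                                                names=["structure", "level"])
    return SignalTable(means=means, per_level=per_level)
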