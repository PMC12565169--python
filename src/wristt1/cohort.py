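"""Cohort-level simulation: many subjects, written to disk or kept in memory.

Seeding rule: a single master seed builds a ``numpy.random.SeedSequence``;
child sequences spawned in a fixed order drive (1) the cohort-level draws
(group sizes are fixed, but CTS status, demographics) and (2) one per-subject
stream each, so any subject can be re-rendered independently and the cohort
is bit-reproducible for a given master seed.

Each subject's truth row also carries a derived ``GCW`` T1: the variable-flip-
angle fit applied to the area-weighted mixture of the tissue SPGR signals
(weights = schematic mid-level tissue areas). This is what the global wrist
contour measures in the noiseless limit, and it lets cohort-level studies run
at truth level without rendering images.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .phantom import (PhantomStudy, SubjectTruth, peak_signal, render_phantom,
                      sample_subject_truth, wrist_label_mask)
from .priors import GroupT1Prior, default_t1_prior
from .protocol import DEFAULT_PROTOCOL, AcquisitionProtocol
from .relaxometry import fit_t1_linear, spgr_signal
from .tissues import GCW, TissueClass

#: Cohort composition defaults: published sample sizes and CTS prevalence.
N_PATIENTS = 36
N_CONTROLS = 69
CTS_FRACTION = 16 / 36


def tissue_area_weights(protocol: AcquisitionProtocol = DEFAULT_PROTOCOL,
                        level: int | None = None) -> dict[str, float]:
    """Fractional area of each tissue in the schematic wrist.

    ``level=None`` returns mid-level weights; an integer selects that slice.
    """
    lv = protocol.n_levels // 2 if level is None else level
    mask = wrist_label_mask(protocol.image_shape, level=lv,
                            n_levels=protocol.n_levels)
    inside = mask > 0
    total = int(inside.sum())
    return {t.name: float((mask == t).sum()) / total for t in TissueClass}


def per_level_weights(protocol: AcquisitionProtocol) -> list[dict[str, float]]:
    return [tissue_area_weights(protocol, lv) for lv in range(protocol.n_levels)]


def mixture_t1(truth: SubjectTruth, protocol: AcquisitionProtocol,
               weights: dict[str, float] | list[dict[str, float]]) -> float:
    """VFA-fitted T1 of the area-weighted tissue signal mixture.

    This is exactly what the global wrist contour measures in the noiseless
    limit: with per-level weight dicts, the per-level area-weighted means are
    averaged across levels before fitting, mirroring the ROI aggregation
    order.
    """
    alphas = np.asarray(protocol.flip_angles_deg)
    weight_list = weights if isinstance(weights, list) else [weights]
    mixed = np.zeros_like(alphas, dtype=float)
    for wdict in weight_list:
        for name, w in wdict.items():
            mixed += w * spgr_signal(truth.m0[name], truth.t1_ms[name],
                                     protocol.tr_ms, alphas)
    mixed /= len(weight_list)
    res = fit_t1_linear(mixed, alphas, protocol.tr_ms)
    return res.t1_ms


def sample_cohort_truth(n_patients: int = N_PATIENTS, n_controls: int = N_CONTROLS,
                        cts_fraction: float = CTS_FRACTION,
                        prior: GroupT1Prior | None = None,
                        protocol: AcquisitionProtocol = DEFAULT_PROTOCOL,
                        seed: int | np.random.SeedSequence = 0,
                        noise_sigma_frac: float = 0.0,
                        ) -> tuple[list[SubjectTruth], pd.DataFrame]:
    """Sample all subjects' ground truth; no images rendered.

    Returns the truth objects and a tidy DataFrame (one row per subject) with
    demographics, per-tissue true T1, the derived GCW mixture T1, the noise
    sigma, and the per-subject child seed.
    """
    if n_patients < 1 or n_controls < 1:
        raise ValueError("cohort needs at least one subject per group")
    prior = prior if prior is not None else default_t1_prior()
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    n_total = n_patients + n_controls
    cohort_ss, *subject_ss = ss.spawn(n_total + 1)
    cohort_rng = np.random.default_rng(cohort_ss)
    weights = per_level_weights(protocol)

    truths: list[SubjectTruth] = []
    records: list[dict] = []
    for i in range(n_total):
        group = "patient" if i < n_patients else "control"
        cts = bool(cohort_rng.random() < cts_fraction) if group == "patient" else False
        sub_seed = int(subject_ss[i].generate_state(1, dtype=np.uint32)[0] % (2 ** 31))
        rng = np.random.default_rng(subject_ss[i])
        sid = f"{'P' if group == 'patient' else 'C'}{i + 1:03d}"
        truth = sample_subject_truth(sid, group, cts, prior, rng)
        if noise_sigma_frac > 0:
            truth.noise_sigma = noise_sigma_frac * peak_signal(truth, protocol)
        truths.append(truth)
        rec = {"subject_id": sid, "group": group, "cts": cts,
               "age_years": truth.age_years, "sex": truth.sex,
               "noise_sigma": truth.noise_sigma, "seed": sub_seed}
        for t in TissueClass:
            rec[f"t1_{t.name}"] = truth.t1_ms[t.name]
            rec[f"m0_{t.name}"] = truth.m0[t.name]
        rec[f"t1_{GCW}"] = mixture_t1(truth, protocol, weights)
        records.append(rec)
    return truths, pd.DataFrame.from_records(records)


def render_cohort_subject(truth: SubjectTruth, protocol: AcquisitionProtocol,
                          subject_seed: int) -> PhantomStudy:
    """Render one subject from its per-subject seed (re-render-able in isolation)."""
    return render_phantom(truth, protocol, np.random.default_rng(subject_seed))


def simulate_cohort(n_patients: int = N_PATIENTS, n_controls: int = N_CONTROLS,
                    cts_fraction: float = CTS_FRACTION,
                    protocol: AcquisitionProtocol = DEFAULT_PROTOCOL,
                    seed: int = 0, out_dir: str | Path = "cohort",
                    prior: GroupT1Prior | None = None,
                    noise_sigma_frac: float = 0.01) -> pd.DataFrame:
    """Simulate a full cohort and write it to disk.

    Writes per subject: ``<id>_images.nii.gz`` (4-D: x, y, level, flip-angle
    index), ``<id>_mask.nii.gz`` (integer labels), and a shared
    ``flip_angles.json`` sidecar recording the angle order and TR; plus
    ``cohort.csv`` with the ground truth for every subject.
    """
    import nibabel as nib

    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {out}: {exc}") from exc

    truths, table = sample_cohort_truth(n_patients, n_controls, cts_fraction,
                                        prior, protocol, seed, noise_sigma_frac)
    affine = np.diag([protocol.pixel_mm[0], protocol.pixel_mm[1], 1.0, 1.0])
    for truth, (_, row) in zip(truths, table.iterrows()):
        study = render_cohort_subject(truth, protocol, int(row["seed"]))
        # (level, angle, H, W) -> (x, y, level, angle)
        vol = np.transpose(study.images, (2, 3, 0, 1))
        nib.save(nib.Nifti1Image(vol.astype(np.float32), affine),
                 out / f"{truth.subject_id}_images.nii.gz")
        mask = np.transpose(study.masks, (1, 2, 0)).astype(np.int16)
        nib.save(nib.Nifti1Image(mask, affine),
                 out / f"{truth.subject_id}_mask.nii.gz")
    sidecar = {"flip_angles_deg": list(protocol.flip_angles_deg),
               "tr_ms": protocol.tr_ms, "n_levels": protocol.n_levels,
               "axes": "x, y, level, flip_angle_index"}
    (out / "flip_angles.json").write_text(json.dumps(sidecar, indent=2))
    table.to_csv(out / "cohort.csv", index=False)
    return table


def load_cohort_subject(out_dir: str | Path, subject_id: str,
                        protocol: AcquisitionProtocol,
                        truth: SubjectTruth) -> PhantomStudy:
    """Read one subject's stack and mask back from disk."""
    import nibabel as nib

    out = Path(out_dir)
    vol = np.asarray(nib.load(out / f"{subject_id}_images.nii.gz").dataobj, dtype=float)
    mask = np.asarray(nib.load(out / f"{subject_id}_mask.nii.gz").dataobj)
    images = np.transpose(vol, (2, 3, 0, 1))
    masks = np.transpose(mask, (2, 0, 1)).astype(np.int16)
    return PhantomStudy(subject_id=subject_id, images=images, masks=masks,
                        truth=truth, protocol=protocol)


def truth_from_row(row: pd.Series) -> SubjectTruth:
    """Rebuild a SubjectTruth from a cohort.csv row."""
    t1 = {t.name: float(row[f"t1_{t.name}"]) for t in TissueClass}
    m0 = {t.name: float(row[f"m0_{t.name}"]) for t in TissueClass}
    return SubjectTruth(subject_id=str(row["subject_id"]), group=str(row["group"]),
                        cts=bool(row["cts"]), age_years=float(row["age_years"]),
                        sex=str(row["sex"]), t1_ms=t1, m0=m0,
                        noise_sigma=float(row["noise_sigma"]))
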