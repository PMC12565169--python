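"""End-to-end pipeline: simulate -> aggregate -> fit -> analyze -> agreement.

A :class:`RunConfig` (YAML-serializable) plus a master seed reproduces every
output file bit-identically. Stages write CSV tables to the output directory
and a JSON run log (config hash, seed, library versions, invalid-fit counts).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cohort as cohort_mod
from .agreement import agreement_summary, reader_perturbation
from .cohort import (load_cohort_subject, simulate_cohort, truth_from_row)
from .cohort_stats import contrast_table, cts_subgroup_contrast
from .diagnostics import operating_point, roc, youden_threshold
from .priors import GroupT1Prior, default_t1_prior
from .protocol import AcquisitionProtocol
from .relaxometry import estimate_all_structures
from .roi import signal_table
from .tissues import REPORTED_STRUCTURES

log = logging.getLogger("wristt1")


class StageError(RuntimeError):
    """A pipeline stage failed; message names the stage."""


@dataclass
class RunConfig:
    """Everything a run needs; fully serializable to YAML."""

    n_patients: int = cohort_mod.N_PATIENTS
    n_controls: int = cohort_mod.N_CONTROLS
    cts_fraction: float = cohort_mod.CTS_FRACTION
    noise_sigma_frac: float = 0.01      # Rician sigma as fraction of peak OTHER signal
    fitter: str = "linear"              # "linear" | "nls"
    ci_method: str = "delong"           # "delong" | "bootstrap"
    mask_jitter: int = 1                # px, second-reader contour perturbation
    n_reread: int = 20                  # patients re-read for agreement
    prior_family: str = "normal"        # "normal" | "lognormal"
    seed: int = 0
    out_dir: str = "run"
    flip_angles_deg: tuple[float, ...] = (2.0, 5.0, 7.0, 10.0, 12.0, 15.0)
    tr_ms: float = 5.81
    n_levels: int = 3
    image_shape: tuple[int, int] = (96, 80)

    def protocol(self) -> AcquisitionProtocol:
        return AcquisitionProtocol(flip_angles_deg=tuple(self.flip_angles_deg),
                                   tr_ms=self.tr_ms, n_levels=self.n_levels,
                                   image_shape=tuple(self.image_shape))

    def prior(self) -> GroupT1Prior:
        return default_t1_prior(family=self.prior_family)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(_plain(asdict(self)), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    def digest(self) -> str:
        blob = yaml.safe_dump(_plain(asdict(self)), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


# ---------------------------------------------------------------------------
# stages

def stage_simulate(config: RunConfig) -> pd.DataFrame:
    out = Path(config.out_dir)
    return simulate_cohort(config.n_patients, config.n_controls,
                           config.cts_fraction, config.protocol(),
                           seed=config.seed, out_dir=out,
                           prior=config.prior(),
                           noise_sigma_frac=config.noise_sigma_frac)


def stage_fit(config: RunConfig, cohort_df: pd.DataFrame | None = None) -> pd.DataFrame:
    """Aggregate ROI signals and fit T1 per subject and structure."""
    out = Path(config.out_dir)
    if cohort_df is None:
        cohort_df = pd.read_csv(out / "cohort.csv")
    protocol = config.protocol()
    records = []
    for _, row in cohort_df.iterrows():
        truth = truth_from_row(row)
        study = load_cohort_subject(out, truth.subject_id, protocol, truth)
        table = signal_table(study)
        fits = estimate_all_structures(table, protocol, method=config.fitter)
        for structure, res in fits.items():
            records.append({"subject_id": truth.subject_id, "structure": structure,
                            "t1_ms": res.t1_ms, "m0": res.m0, "r2": res.r2,
                            "valid": res.valid, "reason": res.reason,
                            "method": res.method})
    fits_df = pd.DataFrame.from_records(records)
    fits_df.to_csv(out / "subject_t1.csv", index=False)
    return fits_df


def _t1_wide(cohort_df: pd.DataFrame, fits_df: pd.DataFrame) -> pd.DataFrame:
    """Merge per-subject fitted T1 (invalid -> NaN) with demographics."""
    valid = fits_df.copy()
    valid.loc[~valid["valid"].astype(bool), "t1_ms"] = np.nan
    wide = valid.pivot(index="subject_id", columns="structure", values="t1_ms")
    wide.columns = [f"t1_{c}" for c in wide.columns]
    keep = cohort_df[["subject_id", "group", "cts", "age_years", "sex"]]
    return keep.merge(wide.reset_index(), on="subject_id")


def stage_analyze(config: RunConfig, cohort_df: pd.DataFrame | None = None,
                  fits_df: pd.DataFrame | None = None) -> dict[str, pd.DataFrame]:
    out = Path(config.out_dir)
    if cohort_df is None:
        cohort_df = pd.read_csv(out / "cohort.csv")
    if fits_df is None:
        fits_df = pd.read_csv(out / "subject_t1.csv")
    df = _t1_wide(cohort_df, fits_df)

    contrasts = contrast_table(df)
    contrasts.to_csv(out / "contrast.csv")

    roc_rows, op_rows = [], []
    for structure in REPORTED_STRUCTURES:
        col = f"t1_{structure}"
        sub = df.dropna(subset=[col])
        scores = sub[col].to_numpy()
        labels = sub["group"].to_numpy()
        r = roc(scores, labels, ci_method=config.ci_method, seed=config.seed)
        thr = youden_threshold(scores, labels)
        op = operating_point(scores, labels, thr)
        roc_rows.append({"structure": structure, "auc": r.auc,
                         "ci_low": r.ci95[0], "ci_high": r.ci95[1],
                         "ci_method": r.ci_method, "n": len(sub)})
        op_rows.append({"structure": structure, "threshold_ms": thr,
                        "sensitivity_pct": op.sensitivity_pct,
                        "specificity_pct": op.specificity_pct,
                        "tp": op.tp, "fn": op.fn, "tn": op.tn, "fp": op.fp})
    roc_df = pd.DataFrame(roc_rows).set_index("structure")
    roc_df.to_csv(out / "roc.csv")
    op_df = pd.DataFrame(op_rows).set_index("structure")
    op_df.to_csv(out / "operating_points.csv")

    cts_df = cts_subgroup_contrast(df)
    cts_df.to_csv(out / "cts_contrast.csv")
    return {"contrast": contrasts, "roc": roc_df,
            "operating_points": op_df, "cts_contrast": cts_df}


def stage_agreement(config: RunConfig, cohort_df: pd.DataFrame | None = None) -> pd.DataFrame:
    """Re-read a random sample of patients with a jittered second reader."""
    out = Path(config.out_dir)
    if cohort_df is None:
        cohort_df = pd.read_csv(out / "cohort.csv")
    protocol = config.protocol()
    patients = cohort_df[cohort_df["group"] == "patient"]
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xA66]))
    n = min(config.n_reread, len(patients))
    chosen = patients.sample(n=n, random_state=int(rng.integers(2 ** 31)))

    readings: dict[str, list[tuple[float, float]]] = {s: [] for s in REPORTED_STRUCTURES}
    for _, row in chosen.iterrows():
        truth = truth_from_row(row)
        study = load_cohort_subject(out, truth.subject_id, protocol, truth)
        t1_reader1 = estimate_all_structures(signal_table(study), protocol,
                                             method=config.fitter)
        t1_reader2 = estimate_all_structures(
            reader_perturbation(study, config.mask_jitter, rng), protocol,
            method=config.fitter)
        for s in REPORTED_STRUCTURES:
            if t1_reader1[s].valid and t1_reader2[s].valid:
                readings[s].append((t1_reader1[s].t1_ms, t1_reader2[s].t1_ms))
    rows = []
    for s in REPORTED_STRUCTURES:
        res = agreement_summary(np.asarray(readings[s]))
        rows.append({"structure": s, "icc": res.icc,
                     "icc_ci_low": res.icc_ci95[0], "icc_ci_high": res.icc_ci95[1],
                     "band": res.reliability_band, "bias_ms": res.bias,
                     "loa_low": res.loa95[0], "loa_high": res.loa95[1],
                     "n": res.n})
    agr = pd.DataFrame(rows).set_index("structure")
    agr.to_csv(out / "agreement.csv")
    return agr


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage; returns the in-memory bundle of result tables."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    bundle: dict = {}
    stages = [("simulate", lambda: stage_simulate(config)),
              ("fit", lambda: stage_fit(config, bundle.get("cohort"))),
              ("analyze", lambda: stage_analyze(config, bundle.get("cohort"),
                                                bundle.get("fits"))),
              ("agreement", lambda: stage_agreement(config, bundle.get("cohort")))]
    for name, fn in stages:
        log.info("stage %s", name)
        try:
            result = fn()
        except Exception as exc:
            _write_log(config, bundle, failed_stage=name, error=str(exc))
            raise StageError(f"stage {name!r} failed: {exc}") from exc
        if name == "simulate":
            bundle["cohort"] = result
        elif name == "fit":
            bundle["fits"] = result
        elif name == "analyze":
            bundle.update(result)
        else:
            bundle["agreement"] = result
    _write_log(config, bundle)
    return bundle


def _write_log(config: RunConfig, bundle: dict, failed_stage: str | None = None,
               error: str | None = None) -> None:
    import scipy
    import statsmodels

    fits = bundle.get("fits")
    invalid = {} if fits is None else (
        fits.loc[~fits["valid"].astype(bool)].groupby("structure").size().to_dict())
    payload = {"config": _plain(asdict(config)), "config_sha256": config.digest(),
               "seed": config.seed,
               "versions": {"numpy": np.__version__, "scipy": scipy.__version__,
                            "pandas": pd.__version__,
                            "statsmodels": statsmodels.__version__},
               "invalid_fit_counts": {str(k): int(v) for k, v in invalid.items()},
               "failed_stage": failed_stage, "error": error}
    Path(config.out_dir, "run_log.json").write_text(json.dumps(payload, indent=2))


# ---------------------------------------------------------------------------
# report formatting

def fmt_median_iqr(median: float, q1: float, q3: float) -> str:
    """Render '994 (926-1085)' from a median and quartiles (ms, rounded)."""
    return f"{median:.0f} ({q1:.0f}–{q3:.0f})"


def fmt_auc_ci(auc: float, ci: tuple[float, float]) -> str:
    """Render '0.85 (0.77, 0.93)'."""
    return f"{auc:.2f} ({ci[0]:.2f}, {ci[1]:.2f})"


def fmt_count_percent(k: int, n: int) -> str:
    """Render '16 (44)' — count with integer percentage."""
    if n <= 0:
        raise ValueError("denominator must be positive")
    return f"{k} ({round(100 * k / n)})"


def fmt_p(p: float) -> str:
    return "<0.001" if p < 0.001 else f"{p:.3g}"


def make_report(bundle_or_dir) -> str:
    """Human-readable summary of a completed run."""
    if isinstance(bundle_or_dir, (str, Path)):
        out = Path(bundle_or_dir)
        bundle = {name: pd.read_csv(out / f"{fname}.csv", index_col=0)
                  for name, fname in [("contrast", "contrast"), ("roc", "roc"),
                                      ("operating_points", "operating_points"),
                                      ("agreement", "agreement"),
                                      ("cts_contrast", "cts_contrast")]}
        fits = pd.read_csv(out / "subject_t1.csv") if (out / "subject_t1.csv").exists() else None
        bundle["fits"] = fits
    else:
        bundle = bundle_or_dir
    for key in ("contrast", "roc", "agreement"):
        if key not in bundle or bundle[key] is None:
            raise ValueError(f"bundle is missing the {key!r} table")

    lines = ["Wrist native-T1 cohort report", "=" * 30, "",
             "Native T1 by structure, median (IQR) ms:"]
    c = bundle["contrast"]
    for s, row in c.iterrows():
        lines.append(
            f"  {s:<5} patients {fmt_median_iqr(row['patient_median'], row['patient_q1'], row['patient_q3']):>16}"
            f"  controls {fmt_median_iqr(row['control_median'], row['control_q1'], row['control_q3']):>16}"
            f"  p {fmt_p(row['p_raw'])}  adjusted p {fmt_p(row['p_adjusted'])}")
    lines += ["", "ROC (lower T1 = disease), AUC (95% CI):"]
    for s, row in bundle["roc"].iterrows():
        lines.append(f"  {s:<5} {fmt_auc_ci(row['auc'], (row['ci_low'], row['ci_high']))}")
    if "operating_points" in bundle and bundle["operating_points"] is not None:
        lines += ["", "Operating points (Youden):"]
        for s, row in bundle["operating_points"].iterrows():
            lines.append(f"  {s:<5} T1 < {row['threshold_ms']:.0f} ms: "
                         f"sensitivity {row['sensitivity_pct']:.0f}%, "
                         f"specificity {row['specificity_pct']:.0f}%")
    lines += ["", "Inter-reader agreement, ICC (95% CI):"]
    for s, row in bundle["agreement"].iterrows():
        lines.append(f"  {s:<5} {row['icc']:.3f} ({row['icc_ci_low']:.3f}, "
                     f"{row['icc_ci_high']:.3f})  {row['band']};  "
                     f"bias {row['bias_ms']:.1f} ms, "
                     f"LoA ({row['loa_low']:.1f}, {row['loa_high']:.1f})")
    fits = bundle.get("fits")
    if fits is not None:
        bad = fits.loc[~fits["valid"].astype(bool)]
        if len(bad):
            lines += ["", "Invalid fits:"]
            for s, k in bad.groupby("structure").size().items():
                lines.append(f"  {s}: {k}")
    return "\n".join(lines) + "\n"
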