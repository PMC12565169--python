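# wristt1

Synthetic variable-flip-angle (VFA) wrist T1 mapping and cohort analysis.

Native T1 — the longitudinal relaxation time of tissue measured without
contrast — is reduced in the wrist structures of patients with transthyretin
cardiac amyloidosis, plausibly because lipid-enriched amyloid deposits shorten
local relaxation. Testing that kind of claim requires a chain of machinery:
a multi-flip-angle spoiled gradient-echo (SPGR) acquisition, per-structure
region-of-interest (ROI) signal aggregation, VFA T1 estimation, and a battery
of group statistics. `wristt1` implements that chain end-to-end over fully
synthetic cohorts with known ground truth, so every stage can be validated
exactly — a testbed for methodologists and a teaching pipeline for
quantitative MRI relaxometry.

## The model

The steady-state SPGR magnitude signal at flip angle α, repetition time TR
and relaxation time T1 is

    S(α) = M0 · sin α · (1 − E1) / (1 − E1 · cos α),   E1 = exp(−TR / T1),

with M0 absorbing proton density, coil gain and fixed-TE T2\* decay. The
canonical DESPOT1 linearization turns the six per-angle ROI means into a
straight line,

    S/sin α = E1 · (S/tan α) + M0 (1 − E1),

so an ordinary least-squares slope estimates E1 and hence
T1 = −TR / ln(slope); a nonlinear least-squares fit of the forward model is
available as a cross-check. Fitting follows the Model/Results convention:

```python
from wristt1 import VFAT1Model
res = VFAT1Model(signals, flip_angles_deg, tr_ms=5.81).fit("linear")
print(res.summary())     # T1, M0, R², E1, validity
```

Around that core the package provides:

* `phantom` / `cohort` — schematic axial wrist phantoms (six tissue
  compartments: transverse carpal ligament TCL, median nerve MN, flexor
  tendon sheaths SFCT, subcutaneous fat SCF, thenar muscle MTE, plus the
  remaining interior), rendered at 3 slice levels × 6 flip angles
  (2, 5, 7, 10, 12, 15°; TR 5.81 ms) with Rician noise, true T1 drawn from
  published per-group median/IQR summaries; NIfTI + CSV output.
* `roi` — per-level ROI means averaged across levels (per-level mean first,
  then unweighted across levels), including the global wrist contour (GCW).
* `cohort_stats` — Wilcoxon rank-sum contrasts, χ²/Fisher, age- and
  sex-adjusted OLS per structure, Pearson correlation grading.
* `diagnostics` — ROC with the lower-T1-positive orientation, AUC by the
  Mann–Whitney identity, DeLong or bootstrap 95% CIs, operating points.
* `agreement` — simulated second-reader contour jitter, ICC(2,1) with
  F-based CIs, Bland–Altman bias and limits of agreement.

## Worked example

```python
from wristt1 import RunConfig, run_pipeline, make_report

cfg = RunConfig(n_patients=12, n_controls=16, seed=7, out_dir="demo",
                noise_sigma_frac=0.01, n_reread=10)
bundle = run_pipeline(cfg)
print(make_report(bundle))
```

prints (abridged):

```
Native T1 by structure, median (IQR) ms:
  TCL   patients    838 (760–945)  controls   963 (897–1026)  p 0.0434  adjusted p 0.647
  MN    patients 1272 (1131–1377)  controls 1479 (1319–1553)  p 0.0043  adjusted p 0.122
  SCF   patients  1020 (767–1080)  controls 1209 (1163–1382)  p <0.001  adjusted p <0.001
  ...
ROC (lower T1 = disease), AUC (95% CI):
  SCF   0.92 (0.82, 1.00)
  ...
Inter-reader agreement, ICC (95% CI):
  GCW   0.998 (0.980, 1.000)  excellent;  bias 4.0 ms, LoA (-5.7, 13.7)
```

Patients' medians sit below controls' for the connective-tissue structures
(the simulated disease effect), the raw rank-sum p values flag those
contrasts, and the adjusted p values show what survives an age/sex
adjustment at this small n. The AUC rows quantify how well each structure's
T1 separates the groups when low T1 is called disease-positive; the ICC rows
show that a one-pixel contour perturbation barely moves the estimates for
large ROIs. At `noise_sigma_frac=0` the fitted T1 values reproduce the
generator's truth table to 1e-6 relative.

The same pipeline runs from the shell:

```sh
wrist-t1 all --seed 7 --out demo --n-patients 12 --n-controls 16
```

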