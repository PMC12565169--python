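# Methods

## Signal model and estimation

The forward model is the steady-state spoiled gradient-echo (SPGR) magnitude
signal, S(α) = M0 sin α (1 − E1)/(1 − E1 cos α) with E1 = exp(−TR/T1).
Echo-time effects are not modelled: with a single TE the T2\* factor is a
constant multiplier that folds into M0. B1 (flip-angle) miscalibration and
slice-profile effects are likewise outside the model — nominal angles are
taken as true — so the simulated data are, by construction, exactly
identifiable by the estimator. That is deliberate: the package's purpose is
to validate the analysis chain against known truth, not to emulate scanner
physics.

Two estimators are provided.

* **linear** (default): the DESPOT1 linearization, OLS of y = S/sin α on
  x = S/tan α; slope = E1, T1 = −TR/ln(slope), M0 = intercept/(1 − E1).
  A fit is valid only when every signal is positive and the slope lies in
  (0, 1); anything else is flagged with a reason code
  (`slope_out_of_range`, `nonpositive_signal`, `too_few_angles`) and carries
  NaN estimates. Invalid fits are propagated, never imputed; downstream
  tables drop them per structure and report the retained n.
* **nls**: nonlinear least squares of the forward model over (M0, T1),
  initialized from the linear fit (or a mid-range heuristic when that is
  invalid), T1 bounded to [1, 10000] ms, tolerances 1e-14. In the noiseless
  limit both estimators agree to machine-level precision; under Rician noise
  the NLS fit minimizes the forward-model residual directly.

A note on a non-obvious failure mode: a *constant* signal across these six
angles does not produce an out-of-range slope. The linearized points then lie
on y = √(c² + x²), whose OLS slope is ≈ 0.995 at this angle range — i.e. a
nearly flat signal profile is approximately consistent with a long finite T1
(~1200 ms at TR 5.81 ms). The validity flag therefore cannot be relied on to
catch saturated or degenerate profiles; the R² diagnostic is reported for
that purpose.

## Synthetic cohorts

**True-T1 priors.** Group summaries are available only as median and
interquartile range per structure, which does not identify a distribution
family. The default family is normal, quantile-matched (location = median,
scale = IQR/1.349) and truncated at zero; a log-normal alternative matched
the same way on the log scale is available (`prior_family="lognormal"`).
Truncation matters only for the thenar muscle (location 185 ms, scale
~96 ms): its truncation point sits at −1.9 sd and biases the sampled median
up by ~1.7%. All other tissues reproduce their configured quartiles to well
under 1%.

The patient subcutaneous-fat prior is stratified by carpal-tunnel-syndrome
status (median 885 vs 1041 ms), mirroring the reported subgroup split;
controls are never assigned CTS. The interior compartment outside the five
named structures ("OTHER") has no published summary of its own and uses the
global-wrist values, since the global contour is dominated by un-named
interior tissue. The global contour (GCW) itself is never sampled — it is
always *derived*, either by aggregating the union region of a rendered image
stack or, at truth level, by fitting the per-level area-weighted mixture of
the compartment signals (both give the same value in the noiseless limit).

**Demographics.** Patients: age ~ N(78, 9²) years, P(male) = 32/36;
controls: age ~ N(43, 14²), P(male) = 24/69; ages clipped to [18, 100].
CTS status is Bernoulli(16/36) per patient. These feed only the adjustment
regression and subgroup contrast. Default cohort size is 36 patients / 69
controls.

**Geometry.** The axial wrist is schematic: an ellipse ringed by
subcutaneous fat, with the ligament band, nerve, tendon sheaths and thenar
muscle as interior ellipses and a 7%-per-level distal contraction. The
analysis consumes only per-ROI mean signals, so anatomical fidelity is
irrelevant to the quantities under study; what the layout does provide is
realistic *relative* ROI sizes (the median nerve is by far the smallest
structure, ~1% of the wrist area) and tissue adjacency, both of which drive
the reader-agreement behaviour below.

**Noise.** Magnitude images receive Rician corruption:
|S + σg₁ + iσg₂| with independent unit normals. σ is configured as a
fraction of the subject's peak OTHER-tissue SPGR signal across the
protocol's angles (`noise_sigma_frac`, default 0.01). The fraction is
referenced to the peak *signal*, not to M0: at TR 5.81 ms the SPGR signal is
only ~3–5% of M0 over these angles, so a fraction of M0 would be an opaque
unit (1% of M0 ≈ 20% of peak signal). No acquisition SNR was available to
match; the default is chosen so that both the noiseless contract (σ = 0,
exact recovery) and a realistically noisy regime are exercised.

**Seeding.** One master seed builds a `numpy.random.SeedSequence`; the first
child drives cohort-level draws and each subject gets its own spawned child,
so subjects can be re-rendered in isolation and the whole cohort — CSV bytes
and image arrays — is reproducible from the master seed.

## Statistics

* Group contrasts: two-sided Wilcoxon rank-sum (Mann–Whitney), exact by
  enumeration when the pooled sample is ≤ 12 without ties, otherwise the
  tie-corrected normal approximation with continuity correction.
* Categorical 2×2 tests: Fisher's exact when any expected cell is < 5,
  otherwise χ² with continuity correction.
* Adjustment: per structure, OLS of T1 on group + age + sex; the adjusted p
  is the two-sided t-test on the group coefficient. The mirrored framing —
  logistic regression of disease status on T1, age, sex — is provided as
  `amyloid_status_logit` for sensitivity analysis; the OLS form is primary.
  No multiple-testing correction is applied across the six structures;
  p values are reported as-is.
* Correlation: Pearson r, graded on |r| (> 0.5 strong, 0.3–0.5 moderate,
  < 0.3 weak).
* ROC: orientation fixed to lower-T1-positive (never auto-detected, which
  would bias AUC upward); positive call at a threshold is *strictly below*;
  AUC via the Mann–Whitney identity with ties counting ½; 95% CI by DeLong
  structural components by default or a 2000-resample stratified percentile
  bootstrap. With zero estimated variance (perfect separation) the variance
  is floored at 1/(4mn) and the result flagged degenerate.
* Agreement: ICC(2,1) — two-way random effects, absolute agreement, single
  measure — with F-based 95% CI (via pingouin), bands 0.5/0.75/0.9; Bland–
  Altman bias ± 1.96·SD of reader differences. The second reader is
  simulated by per-structure mask jitter (random 1–j px erosion, dilation or
  translation), because disagreement in a manual-contouring design arises
  from contours, not from the images. With 1-px jitter at the default matrix
  the smallest structure (median nerve) lands near the moderate/good ICC
  boundary (~0.74) while all larger structures exceed 0.95 — reproducing the
  ordering reliability studies of this design report, where the smallest
  ROIs have the lowest ICCs.

## Validation scale and what it shows

Statistical-calibration checks run at truth level (sampled true T1 per
subject) rather than through image rendering: the noiseless render-aggregate-
fit chain is exact to 1e-6 (verified separately end-to-end at small n), so
cohort-level distributional properties are unchanged by skipping it, and the
suite stays fast. Problem sizes used by the test suite: 500 null replicates
at n = 36/69 for type-I calibration of the adjusted regression and rank-sum
tests (0.05 ± 0.02); 200 simulated cohorts for effect-direction recovery;
50000 draws per cell for prior fidelity; 20 re-read subjects for agreement.

One documented tension: with priors quantile-matched to the published
per-group SFCT summaries, the implied separation gives a true AUC of about
0.766 under *any* two-parameter location-scale family — below the published
AUC of 0.85 (CI 0.77–0.93). The published point estimate is therefore not
recoverable from the published quartiles alone; the real data's shape (or
the pairing of its tails) must differ from any quantile-matched model. The
simulation reports what the quartiles imply rather than tuning the generator
to reproduce the headline number.

## Known limitations

* No B1 mapping, slice-profile, fat–water chemical shift, motion, or
  registration effects; contours are shared across flip angles.
* The thenar muscle is simulated as just another compartment with a low
  apparent T1; the fat–muscle partial-volume physics behind such values is
  not modelled.
* The schematic geometry makes the GCW mixture value sensitive to the
  compartment area fractions, which are stylized; GCW group *direction* is
  meaningful, its absolute level is not.
* Reader jitter is morphological and integer-valued; sub-pixel contour
  disagreement is not representable.
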