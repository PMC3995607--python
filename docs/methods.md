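# Methods

This note documents the models implemented in `pulmopet`, the design of the
synthetic data that exercises them, the calibrations and numerical choices,
and what the test suite does and does not establish about real data.

## Coordinate and unit conventions

Volumes are 3-D arrays indexed `(x, y, z)`: `x` left-right, `y`
anterior-posterior, `z` inferior-superior (higher index = more cranial).
Voxel indices are 0-based; world position = origin + index × spacing (mm).
CT is in Hounsfield Units, PET activity in Bq/mL (kBq/mL accepted with
explicit conversion), SUV dimensionless, dose in Gy or CGE.  When PET or
dose grids differ from the CT grid they are resampled to it by trilinear
interpolation before masking, because the lung ROI is CT-derived.

## SUV computation

`SUV = activity × body_weight_g / (injected_dose_Bq × 2^(−t/T½))` with
`t` the injection-to-scan interval in minutes and `T½ = 109.771` min for
¹⁸F.  The decay correction references scan start; per-bed-position correction
is out of scope.  Tissue density is taken as 1 g/mL.  A volume already
tagged as SUV is rejected rather than silently re-scaled, and the conversion
is logged, so whether the correction has been applied is always explicit.

## Lung ROI

* **Parenchyma**: Otsu threshold on HU clipped to [−1000, 200] — the
  canonical automatic choice for a bimodal air/soft-tissue histogram.  If the
  Otsu value falls outside (−900, 0) HU a fixed fallback of −400 HU is used;
  both can be overridden (`threshold=`, CLI `--config`).  Components
  touching the lateral (x/y) image border are discarded as exterior air, the
  two largest 26-connected components are kept (stricter connectivities
  fragment lungs along thin bridges), and a radius-2 closing fills vessels.
  Fewer than two interior candidate components is an error suggesting the
  threshold override, never a silently empty mask.
* **Airway**: 6-connected region growing through voxels below −950 HU from
  the most superior cluster inside the medial third of the axial plane,
  dilated by one voxel.  6-connectivity prevents leakage through the thin
  airway wall.  A missing seed yields an empty mask plus a logged warning.
* **Exclusions**: spill-over / cold-spot / tumor ROIs are file inputs
  (uint8 NIfTI), reproducing the study's manual-contouring step as data; the
  final ROI is parenchyma − airway − ∪exclusions, with every subtraction and
  its voxel delta recorded in the mask provenance.  An empty final ROI is an
  error.

## Biomarker panel

Mean, SD (denominator n − 1), max and the 80/90/95th percentiles over
exactly the ROI voxels.  The percentile is linear interpolation between
order statistics at rank `1 + (p/100)(n − 1)` — the common default in
scientific software; the estimator is a parameter for sensitivity checks.
A single-voxel ROI reports SD = 0 with a warning.

## Dose metrics

MLD is the mean dose over ROI voxels; `Vx` is the percentage of ROI voxels
with dose **strictly above** x (following the planning phrase "irradiated to
above"); ties at the threshold are measure-zero on real grids but the
semantics are pinned by tests.  Proton dose converts to CGE by a constant
RBE of 1.1; double conversion is rejected via the unit tag.

## Phantom generator

Geometry is specified as fractions of the grid so any shape ≥ 48³ works;
the default is 128³ at 2.5 mm isotropic (≈10⁵ lung voxels).  A soft-tissue
thorax ellipsoid (40 HU) in air (−1000 HU) contains two lung ellipsoids
(−800 HU), a branching central airway (trachea radius ≈9.6 mm, main bronchi
≈6 mm, ending short of the lungs as the bronchial wall does), an optional
intra-lung tumor (soft-tissue density, SUV 6.0), and an optional cardiac hot
sphere (SUV 3.0) adjacent to the lung.  CT gets N(0, 20 HU) noise and a
1.2 mm partial-volume blur.

The clean lung SUV texture is a stationary Gaussian random field
(kernel σ = 15 mm) rank-mapped to the requested marginal distribution, so
the empirical lung-value distribution equals the designed one exactly, and
a 4-voxel shell around the lung continues the same field.  The correlation
length is set well above the PET point-spread width (default FWHM 7 mm,
typical of whole-body PET) so resolution blurring — applied to the whole PET
volume — perturbs the percentile panel only marginally and boundary voxels
mix with statistically identical neighbours rather than a constant
background.  The diaphragm cold spot multiplies a basal lung band by 0.55
*after* the blur, as an attenuation-reconstruction artifact would appear.
Ground truth carries the exact lung/airway masks, one exclusion mask per
artifact (hot sources dilated to the 3σ extent of the PSF), and the panel of
the unblurred lung values.  The default lognormal has its 95th percentile at
1.20 and log-SD 0.223 (see cohort calibration below).

The dose grid is a smooth cranio-caudal × beam-axis Gaussian falloff
(σ = 55/60 mm) peaking at 66 Gy over the tumor — adequate to exercise the
DVH code, with no claim of dosimetric realism.

## Cohort generator

Per patient: age ~ N(64, 8²) truncated to [35, 90]; V30 ~ N(23.8, 8²)
truncated to [0, 60] (%); SUV95 lognormal with log-mean 0.0861 and log-SD
0.2233, chosen so the population terciles fall at 0.99 and 1.20.  Covariates
are drawn independently (their joint correlation structure in real cohorts
is unknown); categorical covariates and auxiliary uptake/dose/pulmonary
columns are generated with realistic marginals for pipeline exercise.

Two outcome layers are generated on centred, scaled covariates
(SUV95 per 0.1, age per 5 years — the age scale is configuration — V30 per
percent):

* **Graded layer** (logistic): P(grade ≥ 2) = expit(β₀ + 0.40·x_suv +
  0.79·x_age + 0.09·x_v30) with β₀ = logit(0.59) so the simulated incidence
  matches the reported symptomatic fraction; grades are then drawn from the
  reported CTCAE mix (10/31/27/23/1/8 per 100 patients).
* **Hazard layer** (exponential proportional hazards): time-to-symptoms
  T ~ Exp(h₀·exp(0.18·x_suv + 0.34·x_age + 0.05·x_v30)), administratively
  censored at 183 days (the 6-month scoring window).  The baseline hazard
  h₀ = 0.00508/day is calibrated once so that the Kaplan-Meier median time
  to symptoms in the upper two SUV95 terciles is ≈101 days.

The two layers share a single uniform draw per patient (comonotone
coupling), so high-risk patients are both symptomatic and early-onset.  They
are deliberately **not** collapsed into one outcome: a single event process
cannot simultaneously follow the stated logistic model for its 183-day
indicator and the stated proportional-hazards model with this calibration
(the hazard layer's 183-day event fraction ≈0.66 exceeds the logistic
incidence ≈0.59), and parameter-recovery tests for both regressions require
exact marginals.  Consequently a small upper-tail minority of records
(~5%) register an observed onset while the graded layer stays below 2; the
analysis module reports grade/event inconsistencies as a note rather than an
error.  Refits recover both coefficient sets with nominal CI coverage
(checked at 90–99% over 200 replicates of n = 500).

Reader simulation: `reading(s, r) = subject_value(s) × (1 + ε)`,
ε ~ N(0, inter-reader SD), default 10 subjects × 3 readers at 3% — the
repeat-read design the agreement analysis expects.

## Statistics

* **Association**: Pearson chi-squared with Yates continuity correction for
  2×2 tables (uncorrected for larger ones), two-sided Mann-Whitney U for
  continuous covariates.  A zero expected cell is an error advising category
  merging.
* **Logistic**: Newton/IRLS maximum likelihood (tolerance 1e-8, ≤100
  iterations) via statsmodels; two-sided Wald tests; OR = exp(coef) with
  exp(coef ± 1.96·SE) intervals; complete separation (any slope |coef| > 20
  or non-finite SE) raises an error naming the term.  Nagelkerke
  R² = Cox-Snell R² / (1 − exp(2·LL₀/n)).
* **Holm**: step-down sequentially rejective Bonferroni over the six SUV
  predictors; adjusted p-values are monotone and ≥ raw.
* **Backward AIC**: from the full model, repeatedly drop the single term
  whose removal most lowers AIC (penalty k = 2, exposed as a parameter);
  stop when no drop lowers it; ties resolve to the earliest candidate, so
  selection is deterministic given data.  For Cox models the generalised
  AIC uses the partial likelihood (the empty model's partial log-likelihood
  is computed in closed form under Efron tie handling).  Note the
  statistical floor: each null candidate survives with asymptotic
  probability P(χ²₁ > 2) ≈ 0.157, so exact-support recovery with five null
  candidates plateaus near 0.84⁵ ≈ 0.43 regardless of sample size; a larger
  penalty (BIC-like) is available via the parameter when sparser selection
  is wanted.
* **ROC**: AUC as the normalised Mann-Whitney statistic over all threshold
  pairs (identical to the trapezoidal rule on the full curve); variance from
  DeLong's structural components (midrank placements); CI = AUC ± 1.96·SE
  clipped to [0, 1].  The Youden point maximises sensitivity + specificity −
  1 over observed thresholds, ties broken toward higher specificity.
  Constant scores yield AUC 0.5 with a warning and an explicitly undefined
  CI.
* **Recursive partitioning**: hand-written depth-2 CART, Gini impurity,
  equal misclassification costs, candidate thresholds at midpoints of
  consecutive sorted unique values, minimum leaf 5; leaves predict the
  majority class with ties classified symptomatic.  When the outcome is an
  OR-rule of two variables, each cutpoint is identifiable only up to the
  spacing of points whose class that variable alone determines; tests
  measure recovery in that metric.
* **Survival**: Kaplan-Meier per SUV95 tercile (boundaries empirical by
  default, pinned at 0.99/1.2 in paper-compat mode); the stratum median is
  the earliest time with survival ≤ 0.5, reported as absent when never
  reached; pairwise tercile hazard ratios come from a Cox fit on tercile
  indicators.  Cox regression uses lifelines' partial-likelihood maximiser
  with Efron tie handling; zero-variance covariates are pinned to HR 1
  rather than passed to the optimiser; monotone likelihood raises an error.
* **Agreement**: per-reading percent deviation from the subject mean; limits
  of agreement = mean deviation ± 1.96·√MS_within with MS_within the
  within-subject mean square on N − k degrees of freedom (the estimator that
  reproduces the closed form ±1.96·σ_reader for large designs); subjects
  with one reading are excluded with a warning.

All CIs use the fixed 1.96 multiplier.  Complete-case analysis per model;
α = 0.05 two-sided throughout (configurable).

## Problem sizes used by the test suite

Phantom checks run on the default 128³ grid (≈10⁵ lung voxels).  Parameter
recovery uses 20–25 replicates of n = 1500–2000 for bias, and 200 replicates
of n = 500 for CI coverage; selection consistency uses 100 replicates of
n = 2000; DeLong is compared against a 2000-replicate bootstrap at n = 50;
the tercile calibration check uses one cohort of n = 10⁴.

## Limitations

* The phantom has no PET physics (scatter, randoms, reconstruction), no
  respiratory motion, and only schematic anatomy; passing its recovery tests
  shows the segmentation/biomarker chain is self-consistent, not that it
  would segment pathological human CT.
* The cohort simulator assumes independent covariates, an exponential
  baseline hazard and a 6-month administrative censor; real RP onset
  dynamics are not exponential.
* Data-dependent quantities of any particular patient study (its observed
  AUC, Youden point, partition thresholds, tercile hazard ratios, agreement
  limits) depend on that study's data and are covered here only structurally:
  the pipeline produces the same kind of estimates with correct statistical
  behaviour on cohorts of the same design.
* "Manual" exclusion contours are file inputs; no interactive editing is
  provided.
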