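# Methods

This note documents the models and procedures implemented in `svdstrat`,
the assumptions behind them, the defaults that matter, and the places where
the design was genuinely open and a choice had to be made.

## Data model

All voxel-wise quantities live on one shared isotropic template grid
(default 32×32×32 at 2 mm). Per-subject affines are not honoured beyond
the isotropic voxel size: registration to template space is assumed to have
happened upstream, and every module rejects mixed grids with a single
`GridMismatchError`. Volumes round-trip through NIfTI-1 as float64.

The cohort table carries demographics (age, sex, premorbid IQ via NART,
Rankin), TIV, strictly increasing scan times starting at 0, per-visit
cognitive z-scores, and the conversion outcome: `converted` with
`event_time` in years, administratively censored at the 5-year follow-up
horizon. Group membership (preVaD vs non-convertor) is derived from the
converted flag.

## Synthetic cohort generator

The generator's defaults are the study conditions the rest of the package
is tested under; they are not re-tuned per analysis.

* **Atlas**: 12 deterministic spherical ROIs (bilateral putamen, caudate,
  thalamus, hippocampus, frontal white matter, centrum semiovale),
  left/right mirrored across the x mid-plane. It stands in for the
  subcortical/white-matter atlases used in practice; the striatum is the
  putamen+caudate union.
* **Template**: piecewise tissue maps — WM core, GM shell, CSF rim, deep
  grey nuclei overriding the core — plus a periventricular WMH probability
  that decays outward (`0.8 − 1.6·d` in normalised radius), so scaling the
  WMH map changes both lesion intensity and supra-threshold extent.
* **Planted convertor effects**: GM in the left putamen, caudate and
  hippocampus is multiplied by (1 − 0.15) *before* noise; WMH probability
  gains +0.2 (scaled by subtype) in frontal WM; lacune rates are 1.8×
  the background rates. Per-subject variability is a global anatomical
  scale factor ~N(1, 0.05) plus voxel noise (σ = 0.02) inside the brain
  mask, with per-voxel tissue sums renormalised to ≤ 1.
* **Lacunes**: per-ROI Poisson counts; each lacune is a 2-voxel in-ROI blob
  (16 mm³ at 2 mm voxels), so every planted lacune exceeds the 10 mm³
  reporting threshold and incidence has the closed-form presence
  probability 1 − exp(−λ) used as a test oracle.
* **Subtypes**: four profiles along two axes — vascular burden
  (WMH/lacune load) and atrophy (hippocampal/global). Subtype 1 is the
  vascular extreme (white-matter/centrum Jacobian contraction up to 0.20,
  WMH ×1.8, near-average baseline cognition, steep executive/speed
  decline); subtype 4 is Alzheimer's-like (hippocampal contraction 0.25,
  WMH ×0.5, memory-loaded baseline deficits); 2 and 3 interpolate.
  Hippocampal atrophy rates order −0.005 → −0.030 /y from subtype 1 to 4.
  The profiles are illustrative config defaults, not empirical claims.
* **Conversion**: event times are exponential with the subtype hazard
  (0.55/0.50/0.45/0.40 events/y) or the background hazard (0.012/y) for
  planted non-convertors, censored at 5 y. The source study reports only a
  mean time to conversion, not subtype hazards, so these are labelled
  illustrative. Note that an exponential censored at 5 y cannot reproduce
  a mean conversion time above 2.5 y; the exponential was kept as the
  simplest generator producing both censoring and group separation. An
  optional flag snaps conversion dates to visit mid-points, mirroring the
  convention of dating conversion halfway between the diagnosing visit and
  the previous one.
* **Divergence maps**: `rate × (t − mean(t)) + noise`, so each subject's
  series averages to ~0 at the mean scan time — the mid-point-template
  convention. Units are treated as log-volume change, so fitted slopes
  read as fractional change per year.

What the generator does **not** emulate: MR contrast, bias fields, scanner
noise, motion, registration error, anatomically realistic lesion shapes, or
correlated cognitive/imaging noise. Passing tests therefore demonstrate
the correctness and calibration of the analysis machinery on data with the
assumed statistical structure, not performance on real MRI.

## Volumetrics

Tissue volumes count voxels at probability ≥ 0.2 (the WMH map is binarised
at a per-subject threshold, default 0.5 — in practice this threshold is
chosen manually per subject; here it is a fixed stand-in). TCV = GM + WM +
WMH, TIV = TCV + CSF. SVDp = 100·WMH/TCV follows the textual definition
(WMH relative to total cerebral volume) rather than the table label that
mentions GM; the published per-group values match neither ratio of printed
means exactly (mean-of-ratios vs ratio-of-means), which is flagged, not
resolved. Annualised rates are OLS slopes over all available time points.

## Lesion analysis and reliability

Incidence uses a strict `> 10 mm³` intersecting-volume rule. The
reliability report interprets "standard error of mean" as the standard
error of measurement SD(diff)/√2 (the two readings are one line apart; the
choice is documented, not asserted as the original's). "Pearson's
intra-class correlation" is ambiguous, so both a Pearson consistency
coefficient and ICC(2,1) (two-way random, absolute agreement, from ANOVA
mean squares) are reported; ICC(2,1) is the default display.

## Voxel-wise GLM and FWE control

Maps are Jacobian-modulated and smoothed with a separable Gaussian
(σ = FWHM/(2√(2 ln 2)) per axis, zero padding, kernel truncated at 6σ so
interior mass is conserved to ~1e−9). The analysis mask keeps voxels with
mean tissue probability > 0.1 across subjects (the original toolchain's
implicit mask is undocumented; this rule is a stand-in). At each voxel an
OLS fit of value on [group, covariates, intercept] yields
t = c'β̂ / √(σ̂² c'(X'X)⁻¹c); zero-residual-variance voxels get t = 0,
are flagged, and are excluded from the max statistic.

Family-wise error is controlled by **max-statistic permutation with the
Freedman–Lane scheme** (residualise against nuisance covariates, permute
residuals, add the nuisance fit back, refit the full model), with
p_fwe(v) = (1 + #{perm max-t ≥ t(v)})/(1 + B). The observed labelling
counts as one permutation, so p ≥ 1/(1+B). Random-field-theory correction
was deliberately not used: permutation gives exact control under
exchangeability and a testable contract, without smoothness estimation.
One-sided contrasts are run in both directions (deficit and excess).

Edge behaviour: weight-normalised (WWA) smoothing computes
smooth(f·w)/smooth(w) with zero padding and masks voxels whose smoothed
weight falls below 1e−6. With a uniform weight this equals plain smoothing
in the interior and renormalises the kernel mass lost at the grid boundary
— the desired behaviour for masked maps. The WWA construction is cited in
the source literature without a formula; weight-normalised Gaussian
smoothing is the standard reading and is recorded as an interpretation.

## Rate maps

Per-voxel independent OLS of divergence on scan time, for subjects with
≥ 2 time points. An intercept is fitted and reported (whether the original
fit included one is unstated; the mid-point convention makes it near zero).
Tissue-weighted rates are voxel-wise products with the warped tissue maps.

## SVM prediction

Leave-one-out cross-validation. Within each fold, confounds (age, sex,
TIV, NART) are regressed out of every feature using training rows only,
features are centred with training means, and a soft-margin linear SVM is
trained; the held-out decision value and its sign are recorded. "Default
hyperparameters" is realised as C = 1 with a linear kernel (the common
toolbox default), exposed in config. Confound handling by per-feature
residualisation was chosen over appending confounds as features, which
would let the confounds drive the kernel. The decision threshold is 0 with
unweighted classes; class imbalance is addressed only through reporting
balanced accuracy, the mean of sensitivity and specificity. Undefined
ratios (zero denominators) are reported as missing, never as 0. AUC is the
rank statistic with half-credit ties. Permutation significance re-runs the
complete pipeline per label permutation (conservative with respect to
whether the original permuted inside or outside the confound step).
Pooled (not per-fold-averaged) rates are used throughout; with the
published confusion counts this gives 73.15 % balanced accuracy where the
source table prints 73.17 %, consistent with per-fold averaging or
upstream rounding there.

## Subtyping

The literal construction is implemented: Pearson correlations between
subjects' in-mask Jacobian vectors form an n×n matrix, and Euclidean
distances between the *rows* of that matrix (self-correlations included)
feed Ward linkage. A 1−r dissimilarity alternative sits behind a flag, off
by default. Ward uses the Ward.D2 convention (scipy's `ward` on Euclidean
inputs); "cluster ward linkage" is convention-ambiguous and the choice is
logged. The tree is cut at k = 4 by default — the number was chosen
visually in the motivating analysis, so k stays a parameter and the
dendrogram is exported. Cluster labels are renumbered by dendrogram
left-to-right order for determinism; ties in merge heights resolve toward
the earlier merge with a warning.

## Survival

Kaplan–Meier estimation and the log-rank test are delegated to
`lifelines`; the module's unit tests check them against hand-computed
product-limit tables and an event-by-event hypergeometric oracle. The
median convention is the first time with S(t) ≤ 0.5, undefined (NaN) when
the curve never reaches 0.5. The "optimal" vascular-burden threshold
criterion is not stated in the source beyond the sensitivity/specificity
curves; Youden's J (sens + spec − 1, ties to the smallest threshold) is
adopted and logged. The stratified analysis crosses SVM prediction with
burden (SVDp ≥ threshold) into four strata, reports 1 − S(5 y) per
stratum, and tests SVM groups with the log-rank statistic; empty strata
are reported as missing, not raised.

## Cognition

Domain indices are arithmetic means of available component z-scores
(missing components excluded and counted). Longitudinal slopes come from a
two-level linear mixed model (random intercept + slope, unstructured 2×2
covariance, maximum likelihood via `statsmodels MixedLM`); per-subject
BLUP slopes are emitted alongside per-subject OLS slopes, and BLUP
shrinkage guarantees var(LME) ≤ var(OLS). On non-convergence the OLS
slopes are used and tagged. The exact original specification (covariance
structure, ML vs REML) is unstated; ML with unstructured covariance is the
documented choice. Baseline comparisons use two-sample t-tests for
continuous variables and Kruskal–Wallis for ordinal/bounded ones (MMSE,
Rankin by default; configurable — the original does not itemise which
variable got which test), with Bonferroni correction at α/m (a family of
17 variables reproduces the conventional P < 0.003 level). Age-scaling of
raw test scores against published norms is out of scope; synthetic
cognition is generated directly as z-scores.

## Simulation sizes in the statistical acceptance checks

Chosen for statistical resolution at desk scale, and fixed:

* FWER calibration: 500 null datasets, n = 30 subjects on a 16³ grid,
  200 permutations; the any-hit fraction must fall in [0.03, 0.07].
* Decoder: 200 null sets (n = 30, 50 features) for the chance-level band;
  50 seeded default cohorts (97/22, 32³) for planted-effect power.
* Subtype recovery: 50 seeded draws of 22 convertors, ARI ≥ 0.9 required
  in ≥ 90 %.
* Equal-rate null contrast: 99 permutations place the attainable rejection
  rate at 0.04 (reject iff the observed max-t ranks in the top 4 of 100),
  giving the ≥ 95 % silent-run criterion a resolvable margin; 1,000 runs
  keep the binomial noise (σ ≈ 0.6 %) well below that margin.
* Survival: 1,000 null log-rank simulations (n = 60); KM median checked on
  n = 2,000 exponential draws.

## Known limitations

* The synthetic phantom is geometric; anatomical claims verified on it are
  true by construction and say nothing about real anatomy.
* Permutation FWE assumes exchangeability after nuisance residualisation;
  heteroscedastic groups are not specifically handled.
* The LME uses a shared residual variance across subjects and visits.
* No Cox regression or competing risks; the survival module covers what
  the stratified analysis needs.
* Cortical-thickness estimation, segmentation, and diffeomorphic
  registration are upstream of this package and out of scope; Jacobian and
  divergence maps are consumed as given.
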