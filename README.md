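# svdstrat

Stratification of preclinical vascular dementia from template-space MRI.

Patients with symptomatic cerebral small vessel disease (SVD) — lacunar
stroke plus confluent white-matter hyperintensities (WMH) — carry a
substantial risk of converting to dementia within a few years. `svdstrat`
implements, as a reusable and tested Python pipeline, the analysis chain
that turns per-subject template-space imaging (tissue probability maps,
lacune masks, Jacobian determinant maps, longitudinal divergence maps) and
a clinical cohort table into:

* **volumetrics** — tissue volumes at probability threshold ≥ 0.2, total
  cerebral volume TCV = GM + WM + WMH, total intracranial volume
  TIV = TCV + CSF, the composite vascular-burden marker
  SVDp = 100 · WMH / TCV (%), and annualised rates of change (OLS slope
  over all available time points);
* **lesion maps** — lacune overlap maps, per-region incidence tables (a
  subject counts for a region when the intersecting lacune exceeds
  10 mm³), and rater-reliability statistics (SEM, mean variability,
  consistency and absolute-agreement ICC);
* **voxel-based morphometry** — Jacobian-modulated, 6 mm-FWHM-smoothed
  tissue maps entered into a voxel-wise two-group GLM with age, sex,
  lacune volume, TIV and premorbid IQ as covariates; family-wise error
  control by Freedman–Lane max-statistic permutation at *P* < 0.05;
* **rate maps** — per-voxel OLS fit of divergence on scan time
  (fractional volume change per year), tissue weighting, and
  weight-normalised (warped-weighted-average) smoothing;
* **prediction** — leave-one-out linear SVM (C = 1) with per-fold confound
  regression and training-mean centring; total/balanced accuracy,
  sensitivity, specificity, PPV, NPV, rank AUC, and full-pipeline
  permutation *p* values;
* **subtyping** — subject-similarity from Pearson correlations of in-mask
  Jacobian vectors, Euclidean distances between correlation-matrix rows,
  Ward-linkage dendrogram, k = 4 cut, and per-subtype summary tables;
* **survival** — SVDp threshold selection by Youden's J, Kaplan–Meier
  curves, log-rank tests, and four-stratum analysis (SVM prediction ×
  vascular burden) with 5-year conversion probabilities.

Because no such cohort is publicly available, the package ships a
first-class **synthetic cohort generator** that emulates the study design:
97 planted non-convertors and 22 planted convertors carrying a 15 %
grey-matter reduction in the left striatum and hippocampus, excess frontal
WMH, left-biased lacune placement, four anatomical subtypes spanning a
vascular ↔ Alzheimer's-like spectrum, and exponential conversion hazards
censored at 5 years. Every downstream stage is tested against this
generator's ground truth.

## Worked example

```python
import numpy as np
from svdstrat.synthetic import EffectSpec, make_atlas, simulate_cohort
from svdstrat.features import extract_features
from svdstrat.prediction import loo_predict
from svdstrat.volumetry import subject_volumetrics
from svdstrat.survival import kaplan_meier, logrank_test

atlas = make_atlas()                      # 32^3 grid, 2 mm voxels
cohort, subjects = simulate_cohort(EffectSpec(), seed=1, atlas=atlas,
                                   longitudinal=False)

mask = atlas.region_mask("putamen-L+putamen-R+caudate-L+caudate-R+"
                         "hippocampus-L+hippocampus-R")
fm = extract_features([s.tissues.gm for s in subjects], mask)
confounds = np.column_stack([
    [r.age for r in cohort],
    [1.0 if r.sex == "male" else 0.0 for r in cohort],
    [r.tiv_mm3 for r in cohort],
    [r.nart for r in cohort]])
res = loo_predict(fm, [r.converted for r in cohort], confounds)
```

Output of the full script (`seed=1`):

```
cohort: 119 subjects, 29 convert within 5 y
mean SVDp  convertors: 1.86 %   non-convertors: 0.95 %
striatum+hippocampus SVM: total 87.4 %, balanced 77.6 %, AUC 0.76
log-rank SVM+ vs SVM-: chi2 82.6, p 1e-19; median dementia-free survival (SVM+): 2.2 y
```

Reading the numbers: 22 subjects are planted as convertors but conversion
itself is stochastic (exponential hazards), so 29 convert here — a few
planted non-convertors convert from the background hazard, as in a real
cohort. Convertors carry roughly twice the vascular burden (SVDp). The
striatum+hippocampus-masked decoder recovers the planted subcortical
grey-matter deficit well above chance (balanced accuracy 77.6 % against a
50 % chance level), and subjects it flags at baseline convert much sooner
(median dementia-free survival 2.2 years versus no median reached in the
unflagged group; log-rank p ≪ 0.005).

## Command line

```bash
svdstrat simulate  --config cfg.yaml --out sim/
svdstrat volumetry --data sim/ --out volu/
svdstrat vbm       --data sim/ --out vbm/ --tissue gm
svdstrat predict   --data sim/ --out pred/
svdstrat cluster   --data sim/ --out clus/
svdstrat survive   --data sim/ --decisions pred/decisions.csv \
                   --volumetrics volu/volumetrics.csv --out surv/
```

Plus `lesions` and `rates`. All subcommands take `--config`, `--seed`,
`--out` and `--log-level`; configuration keys are documented in
`svdstrat/config.py`.

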