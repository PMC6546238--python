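# deltarad

Multi-center FDG-PET/CT **delta-radiomics** analysis pipeline for early
treatment-response assessment, exercised end to end on a synthetic
multi-cohort study with known ground truth.

## The problem

Radiomics studies of locally advanced NSCLC often pool small retrospective
cohorts from several institutes. Each cohort comes with its own scanners,
voxel spacings, noise levels and clinical case mix, and with paired
FDG-PET/CT scans acquired before and roughly two weeks into
(chemo)radiotherapy. Two questions drive the analysis:

1. **Are the cohorts exchangeable?** If a classifier can tell which cohort
   a patient came from, an external validation tests *transferability* of
   a prognostic model to a different population, not *reproducibility*.
2. **Do image features — or their change between the two scans — carry
   prognostic information for overall survival?**

Because such patient images are not publicly deposited, the package ships
a first-class synthetic study generator so that every stage of the
pipeline is testable against ground truth.

## What the package computes

- **Preprocessing** — PET activity → SUV (body-weight normalization with
  decay correction, SUV = C·w/(D·2^(−t/T½))), cubic resampling of all
  volumes to common grids (1×1×3 mm CT, 4×4×3 mm PET), mask resampling
  with re-binarization, and exclusion of patients whose ROI splits into
  multiple segments.
- **Radiomic features** — morphology, fractal (box counting), local
  intensity peaks (SUVpeak: max mean over a 1 cm³ sphere), first-order
  statistics, discretized-histogram features, the PET intensity-volume
  histogram (MTV_x / TLG_x for x = 10…90 % of SUVmax), six 3D texture
  matrix families (GLCM, GLRLM, GLSZM, NGTDM, GLDZM, NGLDM), plus LoG-
  and wavelet-filtered variants.
- **Delta features** — for each feature f:
  `abs = f_during − f_pre` and `rel = (f_during − f_pre)/f_pre`, giving
  the eight image sets CT-scan1/2, PET-scan1/2, CT-abs/rel, PET-abs/rel.
- **Cohort comparison** — univariate rank-sum/chi-square tests and the
  pairwise *cohort-differences (CD) model*: logistic regression
  predicting cohort membership from radiomic covariates and the two-year
  endpoint (optionally gender + stage dummies), summarized by ROC AUC.
- **Survival modeling** — LASSO-penalized Cox models (repeated 10-fold CV
  for λ; one-standard-error rule), prognostic index PI = Σᵢβᵢxᵢ,
  Harrell's c-index with 95 % CI, train-on-one/validate-on-rest and
  combined 75/25-split experiments, reverse-KM median follow-up, and
  univariable Cox models on the percentage change of the common PET
  metrics (volume, SUVmax, SUVmean, SUVpeak, MTV50 %, TLG50 %).
- **Classifier benchmark** — five classifier families (penalized logistic
  regression, random forest, RBF-SVM, gradient boosting, decision tree)
  on the two-year-survival endpoint, mean test AUC per image set.

## Worked example

The numbered drivers under `analysis/` run the full study on a
half-scale four-cohort synthetic dataset (70 patients, volume-driven
hazard) and write their tables to `results/`:

```bash
cd analysis
python 01_generate_study.py
python 02_extract_features.py
python 03_cohort_comparison.py
python 04_survival_models.py
python 05_classifier_benchmark.py
python 06_univariable_pet.py
```

A run prints, among others:

```
wrote 70 patients ({'cohort1': 25, 'cohort2': 16, 'cohort4': 15, 'cohort3': 14}) ...
univariate: 26/54 pairwise comparisons significant at 0.05 (uncorrected)
CD model (without clinical): AUC range 0.97-1.00
median follow-up (reverse KM): 4.58 y [range 0.08-4.74]
cross-cohort: 14/48 validation c-indices significantly above 0.5; 64 empty-model cells
best mean AUC: 0.776 (rf on PET-scan1)
```

Reading these numbers: the four synthetic cohorts differ in spacing,
noise and PET calibration, so the CD model separates them almost
perfectly — any cross-cohort validation here tests transferability. The
generator's hazard is driven by tumor volume, and the pipeline finds it:
several validation c-indices are significantly above 0.5 and the
two-year classifiers reach AUC ≈ 0.78 on the pre-treatment PET set,
while many image sets still yield the empty model ("–" cells). The
univariable table reports hazard ratios per unit fractional change of
each PET metric with negative mean percentage change (tumors shrink
under treatment).

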