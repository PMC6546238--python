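# Methods

This note documents the models, conventions and design choices behind
`deltarad`, in the spirit of a statistical-software methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## 1. Image model and world coordinates

Volumes are axis-aligned 3D grids with voxel spacing in mm; the center of
voxel (i, j, k) sits at `origin + index·spacing` (0-based indices, array
axes ordered x, y, z). Masks are binary grids on the same geometry;
connected components are counted with 26-neighborhood connectivity, the
most permissive standard 3D convention.

## 2. Preprocessing

**SUV.** PET activity concentration C (kBq/mL) is converted to the
body-weight standardized uptake value

SUV = C · w[g] / (D[kBq] · 2^(−t/T½)),

i.e. the injected dose D is decay-corrected from injection to acquisition
time t (T½ = 109.77 min for ¹⁸F). Tissue density is taken as 1 g/mL, so
SUV is unitless. SUV is linear in C by construction.

**Resampling.** All images are resampled to common grids — 1×1×3 mm for
CT, 4×4×3 mm for PET by default — with tricubic B-spline interpolation on
the world-coordinate grid. The output shape preserves the world-space
extent to within one voxel; out-of-grid samples use nearest-edge padding.
Cubic splines reproduce constants exactly and linear ramps away from the
padded boundary (the edge transient decays by ≈ 0.27 per voxel, so a
~10-voxel margin reaches 1e−6 accuracy; the tests account for this).

**Masks** travel through the same cubic pathway and are re-binarized at
0.5. This deliberately mirrors the intensity channel: a thin structure
can sever at the threshold, producing a multi-segment ROI. Texture
features are ill-defined on fragmented ROIs, so such patients are
excluded; every exclusion is logged with the patient id and returned to
the caller — never silently dropped. Mask resampling preserves sphere
volume to within 15 % for radii ≥ 5 voxels (tested).

## 3. Feature inventory

All features are computed in 3D on the resampled grid. Names follow
`filter_family_statistic` (no filter prefix for unfiltered features),
e.g. `wavelet-LLH_GLSZM_inverse-variance`.

**Discretization.** Texture and histogram features require integer gray
levels. Defaults: fixed bin *number* (32) for CT, fixed bin *size*
(0.25 SUV, anchored at the ROI minimum) for PET — the common conventions
for each modality; both are configurable. The lowest bin edge is
inclusive; the ROI maximum lands in the top bin.

**Morphology.** Volume = voxel count × voxel volume; surface area from a
marching-cubes mesh of the zero-padded mask; sphericity
π^⅓(6V)^⅔/A; compactness V/(√π·A^{3/2}); maximum 3D diameter as the
largest distance between ROI voxel centers (via the convex hull).

**Local intensity.** The global peak (SUVpeak on PET) is the maximum over
ROI voxels of the mean intensity in a 1 cm³ sphere (radius 6.204 mm)
centered at the voxel; sphere membership is tested at voxel centers, and
near the image edge the mean runs over in-image voxels. The local peak
re-centers the sphere at the intensity-maximum voxel (highest sphere
mean among tied maxima).

**First-order statistics** use the population standard deviation. The
standardized moments of a constant ROI are undefined; they are emitted
as 0 by the documented undefined-as-zero convention (unlike genuinely
missing features, which are flagged — see §4).

**Intensity-volume histogram (PET only).** For x ∈ {10, …, 90} %:
MTV_x = volume of ROI voxels with SUV ≥ x %·SUVmax (inclusive
threshold), TLG_x = MTV_x × mean SUV over those voxels. MTV and TLG are
non-increasing in x, and TLG_x ≤ MTV_x·SUVmax.

**Texture matrices.** Six families on the discretized ROI:

- *GLCM*: symmetrized co-occurrences over the 13 unique direction
  vectors at Chebyshev distance 1; merged into one matrix by default
  (per-direction averaging selectable). Statistics: joint maximum/
  energy/entropy, contrast, dissimilarity, inverse difference (moment),
  inverse variance, correlation, autocorrelation, sum average, cluster
  tendency/shade/prominence.
- *GLRLM*: maximal equal-level runs along the same 13 directions,
  merged. Run emphases (short/long × low/high gray), nonuniformities,
  run percentage, run entropy, gray-level and run-length variance.
- *GLSZM / GLDZM*: 26-connected equal-level zones; columns index zone
  size (GLSZM) or zone distance (GLDZM) — the minimum over zone voxels
  of the Chebyshev distance to the ROI border, where surface voxels have
  distance 1 and the image edge counts as border. Statistics mirror the
  run-length set with zone/distance emphases.
  **Inverse variance** for these zone families is defined here as
  Σ p(i,j)/j², inverse-squared size/distance weighting; under this
  convention it coincides numerically with the small-zone /
  small-distance emphasis. (Conventions for "IV" differ between
  implementations; this one is fixed and tested.)
- *NGTDM*: per-level sums of |level − mean of in-ROI 26-neighbors|;
  coarseness, contrast, busyness, complexity, strength. These couple the
  occupancy vector with absolute tone differences, so they are not
  invariant to count rescaling (the other five families are, since their
  matrices are normalized to probabilities first).
- *NGLDM*: dependence counts — the number of 26-neighbors within the
  level tolerance α (default 0); feature weights use j = count + 1 so
  zero-dependence voxels remain finite. Dependence emphases,
  nonuniformities, entropy, variances.

Every statistic of every family is verified against an independent
brute-force enumerator (naive nested loops) on random small ROIs to
1e−9, and the merged direction convention is verified invariant under
90° rotations.

**Fractal.** The ROI intensity range is thresholded at fractions
0.1–0.9; each binary set gets a box-counting dimension (box sizes =
powers of 2 up to half the bounding box; dimension = least-squares slope
of log count vs log 1/size). Features: mean and SD of the per-threshold
dimensions, plus gliding-box lacunarity at the half-range threshold.
*Known limitation:* dyadic box sizes are misaligned with base-3
self-similar objects, so the estimator is biased low on, e.g., a Menger
sponge; it is exact on dyadic self-similar sets (both behaviors are
tested). Estimates are comparative descriptors, not unbiased dimension
estimates.

**Filters.** LoG: the analytic 3D Laplacian-of-Gaussian kernel sampled
at voxel centers in mm (spacing-aware, isotropic in world space), mean-
subtracted so it sums exactly to zero (constants map to 0), applied by
FFT convolution with edge padding; default scale ladder {1, 2, 3, 5} mm;
feeds the first-order statistics group. Wavelet: single-level
undecimated separable 3D transform, order-1 Coiflet by default; sub-band
letters ordered (x, y, z) with L = low-pass; the LLL band carries the
low-pass gain 2^{3/2}; odd axes are edge-padded to even length and
cropped back (the inverse transform is exact from the retained padded
coefficients); feeds the texture group.

## 4. Missing-feature policy

A feature whose definition degenerates (correlation of a constant ROI, a
relative delta with zero baseline) is emitted as *missing with a
machine-readable reason*, never as a silent zero — silent zeros would
corrupt penalized regression. Downstream modeling excludes flagged
features listwise (columns with any missing value are dropped before the
LASSO, along with zero-variance columns; no other pre-filtering).

## 5. Delta features

`abs = during − pre` and `rel = (during − pre)/pre`, elementwise over
identical feature inventories; `rel` is a fraction internally and a
percentage only at reporting time (a shrinking tumor reports a negative
change). Shape features of the during-scan use the during-scan mask.
`abs` is linear in each argument and antisymmetric; `rel` is invariant
to common rescaling of both time points.

## 6. Synthetic study generator

The generator emulates the heterogeneity structure of a retrospective
four-cohort PET/CT study; it is the ground-truth harness for every
downstream stage.

- **Tumors**: ellipsoids (radius drawn per patient, per-axis jitter
  ±20 %, center jitter ±3 mm) in a 64×64×48 mm field of view, with
  texture from a stationary Gaussian random field (white noise smoothed
  at a 4 mm correlation length) so texture families respond to a
  controllable parameter. CT: lung-like background (−700 HU) with a
  soft-tissue tumor (20 HU ± 40 HU texture); PET: low background
  (0.8 SUV) with a smooth hot profile scaled to the drawn SUVmax,
  multiplicative texture, a cohort-level calibration offset, Gaussian
  noise, clipped at 0.
- **Time points**: the during-treatment image shares the pre-treatment
  texture field; the ellipsoid axes shrink by (1 − s)^{1/3} for a drawn
  volume-shrinkage fraction s, uptake scales by a drawn factor, noise is
  fresh. Masks live on the finer CT grid and are resampled onto each
  modality's common grid by the pipeline.
- **Cohorts**: per-cohort voxel spacings, noise SDs, PET calibration
  offsets and clinical covariate distributions (age, gender, stage,
  histology, RT dose, chemotherapy timing, scan intervals). The default
  four cohorts mimic the published pattern of a multi-center NSCLC
  study at half scale: sizes 50/31/27/30 (scalable), Siemens-like
  0.98 mm vs Philips-like 1.2 mm CT pixels, 2–4 mm PET voxels, one
  female-rich and one male-dominated cohort, one cohort with sequential
  chemotherapy and long scan intervals. Tumor radii (6–14 mm) are
  deliberately below clinical volumes so the phantom fits a desk-scale
  field of view; absolute volumes are therefore not comparable to
  clinical tables, while fractional changes are.
- **Survival**: log-hazard = Σ coefficient × standardized ground-truth
  property (volume, log-volume, SUVmax, shrinkage, uptake change);
  event times exponential by default (Weibull shape exposed) with rate
  `baseline × exp(log-hazard)`. Administrative censoring at the
  empirical (1 − target)-quantile of the drawn event times calibrates
  the observed censoring fraction to the target by construction. The
  default outcome process is null (no coefficients), matching a study
  in which no prognostic signal was demonstrable; analyses that need a
  recoverable signal switch on a volume coefficient explicitly.
- **Determinism**: one seed per study; per-cohort seeds are spawned from
  it; regeneration is bitwise identical, and a written study (NIfTI +
  CSV + JSON manifest with all seeds) is byte-identical across reruns.

What the generator does *not* emulate: anatomy, DICOM specifics,
respiratory motion, scanner point-spread functions, reconstruction
artifacts. Passing tests therefore demonstrate the correctness and
calibration of the *pipeline*, not clinical performance on real images.

## 7. Cohort comparison

Continuous clinical variables are compared with the two-sample Wilcoxon
rank-sum test (exact enumeration when both groups ≤ 10 and tie-free,
normal approximation with tie correction otherwise); categorical
variables with the chi-square test on the contingency table without
continuity correction, dropping levels absent from both cohorts.
P-values are deliberately *not* corrected for multiple testing,
mirroring the descriptive usage.

The CD model is an unpenalized logistic regression of cohort membership
on standardized covariates: a small radiomic feature set plus the binary
two-year endpoint, optionally plus gender and overall-stage dummies
(three categories II / IIIa / IIIb-IV with II as reference; stage IV is
folded into IIIb/IV). Patients censored before two years are excluded
and counted. The model is scored *in sample* (apparent AUC), matching
the descriptive CD usage; AUC is computed by Mann-Whitney pair counting
(ties half), its 95 % CI by the Hanley-McNeil variance approximation.
Complete separation is reported as AUC 1.0 with a flag rather than as
divergent coefficients.

## 8. Survival modeling

**c-index.** Harrell's concordance over usable pairs — the earlier time
carries an observed event — with PI ties counting ½. The 95 % CI uses a
leave-one-out jackknife computed in O(n²) from per-subject concordant/
usable sums. "Significant" in validation tables means the CI excludes
0.5. The estimator is verified against exhaustive pair enumeration and
against an independent library implementation.

**Penalized Cox.** Features are standardized on the training cohort
(means/SDs stored and reused verbatim for validation scoring, so
re-scoring the training set reproduces the training PIs exactly). The
LASSO path comes from a coordinate-descent elastic-net Cox solver
(l1-ratio 1, 50 path points, α_min ratio 0.05). λ is chosen by repeated
k-fold cross-validation (default 10 folds; fold count reduced with a
warning when events < folds): per fold, the Verweij–van Houwelingen
cross-validated deviance −2·[ℓ(full) − ℓ(train)] at the train-fold fit
(Breslow tie handling throughout), curves interpolated onto the common
path, averaged over folds and repeats, then the **one-standard-error
rule** picks the largest λ within one SE of the minimum. The 1-SE rule
is the standard stabilizer for repeated CV; with the raw minimum rule
(selectable via `lambda_rule="min"`), measured null runs retained
spurious features in ~25–30 % of seeds, while under 1-SE the null
returns the empty model essentially always and a single true feature
(β = 1, 50 noise features, n = 200) is still recovered in all measured
seeds. The empty model — all coefficients shrunk to zero — is a
legitimate outcome, reported with PI ≡ 0 and a flag (the "–" cells of a
validation table).

The development repeats the CV 200 times at full scale; simulation-based
tests and the acceptance script use 3 repeats, 10 folds at n ≈ 100–200 —
the package's scaled-down problem sizes — which the rate measurements
above show is already stable.

**Experiments.** Train-on-one/validate-on-the-rest over the eight image
sets; a combined cohort with an unstratified simple random 75/25 split;
per-cohort prognostic-index min/median/max summaries. Median follow-up
uses the reverse Kaplan-Meier estimator (deaths censored); a curve that
never reaches 0.5 reports "not reached".

**Univariable PET metrics.** The fractional change of volume, SUVmax,
SUVmean, SUVpeak, MTV50 % and TLG50 % each enters a one-covariate Cox
proportional-hazards fit (Efron likelihood via the fitting library);
reported: HR per unit fractional change with Wald 95 % CI and p, and the
single-covariate c-index.

**Classifier benchmark.** Five families behind one interface with fixed
defaults and no tuning: L2 logistic regression (C = 1, standardized),
random forest (100 trees), RBF-SVM (C = 1, scale gamma, decision-function
scores), gradient boosting, and a decision tree (min split 20). These
are scikit-learn analogues of the glmnet / rf / svm / LogitBoost / rpart
lineup; numerical equivalence with those R defaults is not claimed.
Repetitions use stratified train/test splits (test fraction ⅓); a split
missing a class is resampled and logged; patients censored before two
years are excluded. Identical seeds give identical heatmaps.

## 9. Numerical conventions

- Entropies use log₂; 0·log 0 = 0.
- Probability matrices are normalized before feature computation.
- Breslow partial likelihood handles ties; PI ties in concordance count ½.
- Random number streams: `numpy` Generator seeded explicitly everywhere;
  study-level seeds spawn per-cohort seeds via `SeedSequence`.
- Degenerate inputs (constant ROI, empty model, no usable pairs, absent
  class in a split) follow the documented conventions above instead of
  raising, except where the input is unusable (empty mask, no events).

## 10. Known limitations

- The exact feature formula inventory is this package's own (documented
  above); counts and values are not interchangeable with any in-house
  clinical implementation.
- Apparent (in-sample) CD AUC overstates separability at small n; the
  tests bound this inflation but it is inherent to the design it mirrors.
- The box-counting fractal dimension is biased on non-dyadic
  self-similar structures (see §3).
- The jackknife c-index CI and the Hanley-McNeil AUC CI are
  normal-approximation intervals; bootstrap variants would be preferable
  at very small n.
- The synthetic cohorts' acquisition shifts (calibration offsets vs
  within-cohort noise) separate cohorts more sharply than typical
  clinical heterogeneity; CD AUCs near 1.0 on the default study are
  expected and intended to mark the transferability regime clearly.
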