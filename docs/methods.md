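# Methods

This note documents the models, numerical choices and defaults behind
`deltarad`, and what the synthetic test surface does and does not show.

## Preprocessing

Voxels whose HU falls outside a **closed** window `[-200, 500]` are removed
from the ROI before anything else: metal biliary stents (≳ 2000 HU) would
otherwise dominate every texture statistic.  The window is applied on the
native grid *before* resampling (so stent intensities cannot bleed into
neighbouring voxels through interpolation) and re-applied afterwards to catch
interpolation leakage.  Resampling to isotropic 1 mm voxels uses linear
interpolation for the image and nearest-neighbour for the mask (keeps it
binary); both go through `scipy.ndimage.zoom` with `grid_mode=True`.

Gray-level quantization is **fixed bin count** over the in-mask min–max
range: `level = min(L, floor(L*(v - min)/(max - min)) + 1)`, with a constant
ROI mapping to level 1.  Fixed-count (rather than fixed-width) binning makes
every downstream texture feature invariant under positive affine HU
transforms, which the test suite asserts.  Texture features are extracted at
six level counts, default `{8, 16, 32, 64, 128, 256}`; the six values are
configurable.

## Feature registry

One scan yields exactly 257 features in a frozen order (the registry in
`features/registry.py`): 9 intensity, 8 geometry, and 40 texture features ×
6 level counts.  The identities within each texture family follow the common
IBSI-style definitions.  Conventions worth noting:

- Intensity variance/std are population moments; kurtosis is *excess*
  kurtosis; skewness/kurtosis of a constant ROI are 0 by convention.
- Geometry: volumes are voxel counts × voxel volume.  Major/minor diameters
  come from the principal axes of the in-mask voxel coordinates with the
  solid-ellipsoid normalization `2*sqrt(5)*sqrt(eigenvalue)` (the variance of
  a solid ellipsoid along a semi-axis `a` is `a²/5`, so this is exact for the
  ellipsoidal phantoms; the more familiar `4*sqrt(eigenvalue)` is the 2D
  ellipse factor and underestimates 3D diameters by ~11%).  Eccentricity,
  elongation and orientation are read from the second-moment ellipse of the
  largest-area axial slice; perimeter is the marching-squares contour length
  on that slice.
- GLCM: symmetric, distance 1, the 13 unique 3D directions, **matrix**
  averaged (summed then normalized once).  Correlation of a single-level ROI
  is 1 by convention.  Entropy uses log₂.
- GLRLM: per-direction matrices, features computed per direction then
  averaged (the classic feature-average convention; configurable in
  principle but frozen here).  Run percentage divides by the in-mask voxel
  count.
- GLSZM: zones are 26-connected components of equal level; single matrix.
- NGTDM: 26-neighbourhoods restricted to the mask; coarseness is capped at
  `1e6` when its denominator is exactly zero (flat image).
- A single-voxel ROI has no voxel pairs; all its texture features are
  reported as NaN (flagged missing) rather than raising, so cohort
  extraction survives degenerate post-treatment masks.

Conservation identities are enforced by tests: GLCM probabilities sum to 1;
`Σⱼ j·GLRLM[i,j]` per direction and `Σⱼ j·GLSZM[i,j]` equal the voxel count
exactly; NGTDM `Σ nᵢ` equals the number of voxels with ≥ 1 in-mask
neighbour.  Every texture feature is additionally checked against an
independent brute-force enumeration oracle (plain nested loops in
`tests/_oracles.py`) to 1e-8 relative on random 6³ ROIs.

## Delta features

`DRF = post − pre` per feature; the relative variant divides by the baseline
and flags entries with `|pre| < 1e-8` as missing instead of producing
infinities.  The BL-DRF vector is the 514-entry concatenation
`[pre.* , drf.*]`.  Missing values propagate: a missing input makes the
corresponding delta missing, and pipeline-level screening drops features
missing in > 20% of subjects, median-imputing the remainder.  Deltas are
strictly feature-space constructs — no image registration is performed.

## Feature selection

The screening protocol runs repeated k-fold cross-validation (default
100 × 5; heavier tests use 10 × 5) with **one shared fold plan** per seed so
clinical and radiomic modalities see identical partitions.  Per feature and
fold, a univariate Cox model (survival tasks, scored by validation Harrell
C-index) or univariate logistic model (margin, validation AUC) is fitted on
the training fold and scored on the validation fold; the mean over all
repeats × folds ranks the features.  Features averaging **strictly below
0.5** are dropped (0.5 exactly is kept).  Redundancy pruning walks the rank
order and drops a feature iff its |Spearman ρ| exceeds 0.9 against any
already-*retained* better-ranked feature (mRMR-style; pruning against
retained rather than all earlier features is the design choice).  A constant
feature has undefined ρ and is treated as |ρ| = 0 with a log entry.  The
walk is order-dependent by design and a regression test asserts so.

Step-forward multivariate Cox selection then greedily adds the candidate
maximizing mean cross-validated C-index, requiring **strict** improvement
(no tolerance band), stopping at five features.  Ties break by screening
rank.  Folds with < 2 training events or no comparable validation pairs are
skipped, not failed — they are expected at the ~60-subject cohort sizes this
protocol targets.  If the final full-cohort refit encounters monotone
likelihood (separation is common with near-perfect features at small n), it
is retried with a light ridge penalty (0.1) and the event is logged.

## Survival modelling

The Cox fitter maximizes the Efron-tie-corrected partial likelihood with a
dense Newton solver (step halving, convergence `max|Δβ| < 1e-9`, explicit
separation detection when standardized coefficients exceed 50, overflow
treated as a failed step).  It is written in vectorized numpy because the
selection protocol performs ~10⁵ small fits inside cross-validation;
lifelines' `CoxPHFitter` is the independent reference in the test suite
(coefficients and standard errors agree to < 1e-3) and provides
Kaplan–Meier curves and the log-rank test directly.

Risk scores from the clinical and radiomic models are fused by **z-scoring
each stream with its training distribution and averaging**.  Raw averaging
of Cox linear predictors is ill-posed — the linear predictor scale is
arbitrary across models — so normalization before averaging is a deliberate,
documented choice.  A zero-variance stream contributes 0 after centering.
Risk groups split at the **training median** score (high iff score strictly
above threshold), reused unchanged on validation data.  Horizon labelling at
12/24/36 months marks subjects `event` (event by the horizon), `no_event`
(followed beyond it), or `excluded` (censored before it — their status is
unknown, and exclusion rather than imputation is the censoring-faithful
option).

External validation protocol: survival models are retrained once on the full
discovery cohort, a freeze marker is logged, and everything after the freeze
is evaluation-only; an integration test asserts no fit events follow the
marker.

## mCOM and the immune-algorithm optimizer

The margin model treats R0 as the positive class.  Per modality it trains
three linear classifiers — a margin-maximizing linear SVM whose decision
values are mapped to probabilities by a Platt-style logistic fitted on the
training fold, a logistic regression, and a linear discriminant with
shrinkage-regularized pooled covariance — and fuses all member probabilities
by a weighted arithmetic mean (weights ≥ 0, summing to 1).

The IMIA optimizer evolves candidate solutions (per-modality feature
bitmasks, the three regularization hyperparameters, fusion weights) against
the two objectives (mean fold-validation sensitivity, specificity) at the
0.5 operating threshold.  Each generation: parents are drawn with
probability ∝ 1/(1 + non-dominance rank), elites from the archive join,
every parent produces one hypermutated clone (bit flips at rate 0.15,
log-normal jitter on hyperparameters, multiplicative jitter + renormalization
on weights), clones are evaluated, survivors are chosen by non-dominated
sorting with crowding-distance truncation, and the elitist archive (cap 30)
keeps the mutually non-dominated set.  The operating solution is the archive
member with maximal Youden's J = sensitivity + specificity − 1.  Defaults:
population 50, 100 generations; the test suite and acceptance script run the
reduced budget (population 20, 30 generations, 3 inner folds), which is
ample for the cohort sizes simulated.  All randomness flows from one seed;
two runs with the same seed produce identical archives.

External prediction follows the ensemble protocol: the models trained during
repeated cross-validation are kept and their fused probabilities are
averaged on external subjects with no refitting.  LASSO baselines select
features by L1-penalized logistic regression (penalty via inner CV) feeding
a logistic model and a Platt-calibrated linear SVM; if every coefficient is
shrunk to zero the baseline degrades to an intercept-only prevalence
predictor, logged.

Because the optimizer maximizes a cross-validated objective over hundreds of
candidate solutions, its *chosen* fold-validation Youden J is optimistically
biased even on pure noise; the null-label check therefore bounds the mean
over seeds (measured ≈ 0.15 at n = 200) rather than any single run.

## Synthetic data

The phantom generator emulates contoured tumor volumes on contrast CT:
an ellipsoidal tumor (default radii (12, 10, 10) mm on a 64³ 1 mm grid)
with spatially correlated texture — smoothed white noise with kernel width
equal to the correlation length (default 3 mm), rescaled to σ = 30 HU about
a tumor mean of 60 HU, clipped at ±5σ — on a constant 80 HU background,
optionally pierced by a cylindrical stent at 3000 HU.  Treatment response is
isotropic radius shrinkage (default 0.7) with the texture field held fixed,
mirroring the clinical practice of transferring the pre-treatment contour;
shrinkage 1 reproduces the pre-treatment scan bit-for-bit.

Cohort outcomes follow standard parametric models: survival times
`T ~ Exp(h₀·exp(βᵀx))` (default baseline hazard 0.04/month) under
independent exponential censoring (default 0.02/month, the non-informative
censoring assumption); disease-free survival shares the linear predictor
with hazard multiplied by 1.5 (recurrence precedes death on average; there
is no separate DFS coefficient set); margin status is Bernoulli through a
logistic link, with the coefficients giving log-odds of R1.  CA19-9 is
log-normal (pre-treatment median ≈ 290 U/mL with a wide IQR; the
post/pre-treatment ratio is log-normal with median ≈ 0.2, putting a ≥ 50%
decrease in roughly 70% of subjects) and the resectability mix is ~55%
resectable / 29% borderline / 14% locally advanced / 2% metastatic.  These
marginals are chosen once to match the clinical ranges typical of
NAT-treated pancreatic cancer cohorts.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: anatomy (organs, vessels, duct dilation), contrast
phases, scanner noise spectra and reconstruction kernels, contouring
variability, correlated missingness, and any real coupling between imaging
phenotype and outcome beyond the planted coefficients.  The test surface
demonstrates that each algorithm recovers what was planted under its own
assumptions, not that the clinical effect sizes are reproducible.

## Problem sizes used by tests and the acceptance script

Chosen as the package's own verification conditions: selection recovery runs
20 seeds at n = 300 with 2 active (|β| = 1, standardized) + 30 noise
features under 10 × 5 CV; Cox HR recovery uses 20 seeds at n = 500 (true
HR 3); DeLong null calibration uses 500 simulations at n = 100; mCOM checks
use n = 100 (separable), n = 200 (permuted labels), and n = 150 (two-modality
cohort) at the reduced optimizer budget; oracle equivalence uses ≥ 18 random
6³ ROIs with L ∈ {2, 4, 8}; the end-to-end pipeline smoke test uses a
14-subject discovery / 4-subject validation imaging cohort.

## Known limitations

- No wavelet/filtered-image features, no 2D extraction mode, and no shape
  features beyond the eight listed.
- Cox modelling has no time-dependent covariates, competing risks, or
  sample weights (duplicated rows are a documented error, not a reweighting).
- The discriminant member is linear (pooled covariance); quadratic
  discriminants are out of scope.
- The resampler assumes axis-aligned grids (no oblique affines); NIfTI I/O
  preserves spacing and origin but not full orientation matrices.
- Relative DRFs are undefined for near-zero baselines and are reported
  missing; downstream handling (drop > 20% missing, median-impute) is a
  pipeline policy, not a statistical model of missingness.
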