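# Methods

## Imaging model and preprocessing

A CT volume is a 3D array of Hounsfield units with voxel spacing in mm
(array-index order) and a physical origin; axis 0 is the subject's
left–right axis. Anatomical compartments — the muscle envelope and the
subcutaneous shell — are *inputs* (typically produced by semi-automated
delineation in an external tool), not computed here.

Harmonisation runs in a fixed order: isotropic resampling, Gaussian
smoothing, HU normalization, HU thresholding.

* **Resampling** to cubic voxels (default 1 mm) uses trilinear
  interpolation for images and nearest-neighbour for masks, so masks stay
  binary. Cubic voxels are required because the box-counting grid is
  defined in voxel units; anisotropic voxels would make a "box" a cuboid
  of scale-dependent aspect ratio.
* **Smoothing** is a Gaussian with physically specified width
  (default σ = 1.0 mm), converted per axis to voxel units, reflective
  boundaries. σ = 0 is the exact identity.
* **HU normalization** applies one global *additive* shift so the median
  HU inside the muscle reference mask equals a configurable target
  (default 50 HU). Additive rather than multiplicative because
  inter-scanner HU offsets are approximately additive; the median (not
  mean) makes the reference robust to marbled fat inside the muscle mask.
  The operation is idempotent (exactly so when the reference median is
  representable; otherwise to one float rounding of the median).
* **Thresholding** classifies compartment voxels by HU window: muscle
  [−29, +150] HU, adipose [−190, −30] HU — the ranges in wide clinical use
  for CT body composition; both are configurable. SM = muscle-window
  voxels in the muscle compartment, IMAT = adipose-window voxels in the
  muscle compartment, SAT = adipose-window voxels in the subcutaneous
  shell. Disjoint compartments plus disjoint windows guarantee mutually
  exclusive masks, which the `TissueMaskSet` container enforces.
* **Leg splitting** labels the union mask with 26-connectivity and
  requires exactly two dominant components (≥ 10% of the foreground
  each); ordering by centroid along axis 0 names them left and right.
  Connected components rather than a midline cut keep the split robust
  to off-centre positioning.

IMAT is treated throughout as adipose-range voxels *inside the muscle
compartment*; at CT resolution the intramuscular/intermuscular distinction
cannot be drawn from HU alone, and the downstream indices are agnostic to
it.

## Fractal indices

All three indices derive from one box-counting pass per scale: boxes of
edge ε anchored at array index (0,0,0), partial edge boxes included, a
single grid offset (no offset averaging — determinism and a single pass
were preferred; offset averaging changes values by far less than the
between-subject spread at these mask sizes). A box is occupied when it
contains ≥ 1 foreground voxel; its mass is its foreground count. At every
scale, N(ε) · μ[M(ε)] equals the total foreground count exactly, which the
tests assert.

* FD is the OLS slope of log N(ε) on log(1/ε), natural logarithms (the
  slope is base-invariant). A degenerate profile (all counts equal, e.g. a
  single voxel) reports FD = 0 with R² flagged NaN.
* Λ averages σ²/μ² of occupied-box masses over scales, population
  variance, fixed grid (the gliding-box variant would cost an extra scan
  per scale; the fixed grid reuses the counting pass). No +1 offset is
  added, so a mass-homogeneous tiling gives exactly 0.
* ΔFD splits the ascending scale list into the first ⌈k/2⌉ and last
  ⌊k/2⌋+1 scales (the middle point is shared when k is odd so both OLS
  fits keep ≥ 2 points) and returns the absolute slope difference.

The automatic scale set is powers of 2 from 1 to ⌊min(shape)/4⌋ and needs
at least four scales (hence a minimum extent of 32 voxels for automatic
scales); self-similar fixtures such as the Menger sponge are analysed at
explicit powers of 3, where the level-3 sponge yields FD = log 20 / log 3
to 1e-9, Λ = 0 and ΔFD = 0 — each occupied box at an aligned scale holds
an identical mass by self-similarity. An empty mask is a hard error: FD of
nothing is undefined, and silently reporting 0 would feed degenerate
features downstream.

Per-subject features are the arithmetic mean of the left-leg and
right-leg indices per tissue; a tissue empty in either leg yields missing
(NaN) indices for that tissue only.

## Volumetrics

Volume = voxel count × voxel volume / 1000 (cm³); indices divide by height
cubed, giving cm³/m³ (SMI ≈ 2000–4000 at realistic leg volumes and
heights). Subject volumes are bilateral totals. A ratio with a zero
denominator is reported missing rather than zero so the univariate screen
is not biased toward spurious associations.

## Cohort modelling

The MetS label implements the IDF rule: central-obesity gate (sex-specific
waist cutoff, default 90/80 cm, or BMI > 30 kg/m²) plus at least two of:
fasting glucose ≥ 5.6 mmol/L or diabetes history; BP ≥ 130/80 mmHg or
antihypertensive treatment; triglyceride ≥ 1.7 mmol/L or treatment; HDL-C
< 1.03 (men) / 1.29 (women) mmol/L or treatment. Missing optional
measurements fall back on the corresponding history flag.

Splitting is stratified by outcome with per-stratum round-to-nearest
training counts — strata of 93 and 91 at fraction 0.7 give 65 + 64 = 129
training and 55 test subjects.

Continuous predictors are z-scored on training statistics before any fit,
so odds ratios are per-SD (the scale on which ORs of anthropometric and
imaging variables are mutually comparable); binary predictors stay 0/1.
The univariate screen keeps Wald p < 0.1. Collinearity pruning iterates:
compute VIF (1/(1−R²) from OLS on the other predictors) and pairwise
Spearman |ρ|; while any variable has VIF > 10 *or* sits in a pair with
|ρ| > 0.8, remove one (highest-VIF violator first; within a correlated
pair, the member with the larger univariate p) and recompute. OR rather
than AND of the two conditions is the default (configurable): an exactly
duplicated column violates both, but a structural sum (x₃ = x₁ + x₂) can
have infinite VIF with every pairwise |ρ| below 0.8, and must still be
removable. The loop terminates in at most one removal per candidate.

Multivariable fits are maximum-likelihood (Newton) logistic regressions;
non-convergence and perfect separation raise rather than returning an
unusable fit. Three models share one training set: radiological (exactly
IMR, IMAT FD, IMAT ΔFD), clinical (screened and pruned clinical
candidates), combined (their union).

## Evaluation

AUC is the tie-corrected rank statistic. The operating threshold is chosen
once on training data by the Youden index and frozen for every evaluation
set (per-set re-optimisation would inflate test sensitivity/specificity).
Calibration uses ten equal-width probability bins, empty bins omitted.
Decision curves use NB(pt) = TP/n − (FP/n)·pt/(1−pt) on a 0.01–0.99 grid;
the model's net benefit can never exceed prevalence. ICC is the two-way
random-effects, absolute-agreement, single-measurement form ICC(2,1) with
the F-based 95% CI — the form that penalises systematic inter-rater
offsets, which is what segmentation reliability should measure — with the
conventional bins (≤ 0.40 poor, 0.40–0.60 moderate, 0.60–0.80 good,
> 0.80 excellent).

## Synthetic data

The generators define the conditions under which the pipeline is tested;
all are bit-reproducible from (spec, seed).

* **Menger sponge** (≤ level 5): analytic fixture with exact dimension.
* **Random Cantor dust**: independent per-subcube retention with
  probability p per level; expected dimension log(27p)/log 3, valid for
  p > 1/27. At p = 20/27 and 3 levels the mean fitted FD over 20 seeds
  recovers log 20/log 3 within 0.1.
* **Leg phantom**: two cylinders (muscle core radius 14 voxels, SAT
  annulus 6 voxels, length 48, 1 mm isotropic) with air background, SAT
  ring and marbled core. Marbling thresholds a Gaussian-smoothed white
  noise field at the per-leg quantile matching the requested infiltration
  fraction, so fraction and spatial clustering scale are independently
  tunable. HU means are 50 (muscle) and −100 (fat) with configurable
  noise SD; at zero noise the full preprocessing chain recovers the
  ground-truth masks exactly. The resolved-marbling regime is clustering
  scale ≥ 2 voxels: below that, thresholded sub-voxel smoothing
  degenerates to voxel speckle whose box-count scaling reflects
  discretization, not cluster geometry; within the regime the mean
  measured IMAT ΔFD rises monotonically with the clustering scale, which
  is the handle that makes spatial-patterning effects exercisable.
* **Cohort tables**: per-centre normal/Bernoulli feature distributions
  with the outcome drawn only from a known logistic model on features
  standardized by their pooled generative moments. The default two-centre
  scenario (184 + 74 subjects, magnitudes typical of an elderly
  lower-extremity CT cohort) is a set of scenario parameters for
  documentation realism, not data. Because fitted models standardize by
  *sample* statistics, the per-SD coefficient they estimate differs from
  the generative one by the factor s_sample/s_generative (≈ 1 ± n^{-1/2});
  at n = 500 this leaves Wald 95% CI coverage within [0.92, 0.98].

What the phantoms do *not* emulate: scanner noise physics, beam
hardening, partial-volume gradients at tissue interfaces, anatomical
curvature and inter-muscular fascia geometry. Passing tests therefore
demonstrate correctness of the measurement and modelling chain under
known geometry, not clinical validity on patient data.

## Problem sizes and numerical choices

Tests and the acceptance script use phantoms of ~96×48×48 voxels, 27³
fractal fixtures, cohorts of 184–500 subjects, 20-seed Monte-Carlo
trends, 200-rep coverage and 1000-rep type-I-rate simulations — sizes at
which every stochastic check has comfortable Monte-Carlo margins while
the whole suite runs in well under a minute of CPU for the deterministic
parts. Ties in the Youden scan resolve to the smallest threshold;
exact collinearity caps VIF at 1e12 with the offender flagged; the
box-count profile container validates ascending scales and positive
counts on construction.

## Known limitations

* Single-grid-offset box counting slightly overestimates N(ε) variance
  relative to offset-averaged schemes on very sparse masks.
* The ICC CI comes from pingouin's F approximation; no bootstrap.
* No DICOM ingestion, no automatic compartment segmentation, no penalized
  regression variants; the end-to-end runner simulates its cohort rather
  than reading patient data.
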