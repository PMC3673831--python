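# Methods

This note documents the models and procedures implemented in `copdct`, the
choices made where the design was genuinely open, and what the synthetic
data can and cannot establish.

## Density biomarkers

The emphysema index IN₋₉₅₀ is the percentage of lung-mask voxels in the
inspiratory phase with attenuation **strictly below** −950 HU; a voxel at
exactly −950 HU is not counted.  The air-trapping index is the signed ratio
of expiratory to inspiratory mean lung density (MLD), both in HU; with
normally aerated lung both MLDs are negative and the ratio sits near
0.8–0.9, approaching 1 with gas trapping.  Lung volumes are voxel count ×
voxel volume, reported in liters.

Low-dose screening CT is noisy, so a smoothing step precedes histogram
analysis.  `denoise_volume` applies an isotropic Gaussian kernel specified
by its world-unit standard deviation (default 1.0 mm, applied to both
phases); this is a generic, documented smoothing kernel, not a reconstruction
of any scanner-specific filter.  Phantom ground-truth comparisons run with
smoothing off, since the phantoms are noiseless by default.

## Airway morphometry

1. **Lumen segmentation** — region growing from a seed in air (< −900 HU)
   over `HU < t`, with the threshold raised in geometrically doubling steps
   (5, 10, 20, … HU from −980).  A step whose 6-connected seed component
   more than doubles in volume is treated as a leak into the parenchyma and
   the previous threshold is kept; a leak at the first step flags the
   segmentation as failed rather than raising.  This is a deliberately
   simple whole-tree schedule; per-subtree threshold optimization is out of
   scope.
2. **Centerline** — the lumen mask's Euclidean distance transform D (world
   units) defines a medialness cost `length / (0.25 + D²)` on the 26-
   connected voxel graph.  The main path runs from the root (voxel nearest
   the user seed) to the geodesically furthest voxel along the minimum-cost
   route, which hugs the ridge of D (the airway axis).  Further branches are
   traced iteratively from the furthest remaining voxel back to the existing
   centerline and accepted while their geodesic reach exceeds a pruning
   length (default 3 mm) plus the local radius at the attachment — the
   radius term suppresses corner spurs at open tube ends.  Paths are
   smoothed, recentered on the in-plane lumen centroid (sub-voxel axis
   estimate), and free ends are straightened by extrapolating the adjacent
   interior direction, since the distance ridge flattens within one radius
   of an open end.  Branches split at attachment points; generation labels
   count bifurcations from the root (0 = trachea, 1 = main bronchi, ≥2 =
   measurable).  A voxel-thinning skeletonization was rejected because
   parallel 3D thinning can annihilate perfectly symmetric even-diameter
   tubes — exactly the geometry of calibration phantoms.
3. **Cross-sections** — sites along each branch at fixed arc spacing
   (default 1.0 mm), with the normal taken as the local tangent (central
   differences, one-sided at branch ends).
4. **Wall detection** — 72 equally spaced rays per section in the normal
   plane, HU sampled by trilinear interpolation at 0.1-mm steps.  Per ray,
   the wall is the attenuation peak; the inner boundary is the half-rise
   between the lumen plateau (median of near-center samples) and the peak,
   the outer boundary the half-fall between the peak and the parenchyma
   plateau (median 1–3 mm beyond the peak).  This FWHM-style rule is a
   documented substitute for proprietary intensity-integration detectors and
   is not claimed equivalent.  A ray is missing when the peak rises less
   than 150 HU above the lumen plateau, stands less than 75 HU above the
   parenchyma, or lacks room for the outer fall; missing rays are
   interpolated angularly when ≤25% of rays, otherwise the section is
   excluded as a wall-detection failure (both fractions configurable).
   Pi is the perimeter of the closed polygon through the inner boundary
   points; WA is the outer-polygon area minus the inner-polygon area.
   A 72-gon under-estimates a circle's perimeter by 0.013%, far below the
   detector's own bias, so no chord correction is applied.
5. **Exclusions** — sections on the trachea (generation 0) or main bronchi
   (generation 1), sections within 2 mm of a bifurcation (configurable; no
   published distance exists for this rule), and failed sections are removed,
   with a per-reason tally.  Human visual review of segmentations is
   replaced by these automatic flags.
6. **Pi10** — ordinary least squares of √WA on Pi across the surviving
   sections; `pi10 = intercept + 10·slope`.  At least two sections with
   distinct perimeters are required; otherwise a degenerate-regression error
   is raised.

Accuracy on noiseless phantoms at 0.4-mm voxels: Pi within ~1.5% and WA
within ~5% of the closed forms for a 2-mm-lumen, 1-mm-wall tube; the Pi10
from three tubes of graded caliber lands within 0.03 mm of the closed-form
regression.

## Diagnostic models

COPD is defined spirometrically: FEV₁/FVC strictly below 0.70 (a ratio of
exactly 0.70 is not COPD), graded by FEV₁ %predicted as mild (≥80),
moderate ([50, 80)) or severe (<50).  The published bands stop at 30%; the
range below 30% is mapped to severe here, as the cohorts concerned contain
essentially no such subjects.

The ladder comprises eight logistic models: (1) demographics — age, BMI,
pack-years (untransformed; the log alternative is configurable upstream of
the design frame), current-vs-former smoking; (2–4) demographics plus one
biomarker; (5–7) plus each pair; (8) plus all three.  The emphysema index
enters as ln IN₋₉₅₀ (the raw index is strongly right-skewed), which requires
IN₋₉₅₀ > 0; records violating this are rejected, as are records with any
missing covariate — multiple imputation is deliberately out of scope and the
error lists the offending rows.

Fitting is maximum likelihood via statsmodels (Newton scoring, tolerance
1e−8, 100 iterations), with covariates standardized internally and
coefficients reported on the original scale.  Complete separation and
non-convergence raise typed errors.

**Internal validation** uses Harrell's optimism bootstrap: for each of B
(default 500) resamples, refit the model, score the C-statistic on the
resample and on the original data, and average the difference; the
corrected C is the apparent C minus this optimism.  Shrinkage is uniform:
the slope coefficients are multiplied by the mean bootstrap calibration
slope (logistic slope of the original outcomes on the resample model's
linear predictor), clipped to (0, 1], and the intercept is re-estimated on
the original data with the shrunk linear predictor as offset.  Resamples
with a single outcome class are redrawn (up to 10×, counted in the report).
The C-statistic is the concordance probability (ties count ½), computed by
midranks; its confidence interval is a DeLong normal approximation truncated
to [0, 1].

**Cutoffs and reclassification.**  The operating point maximizes TP+TN over
thresholds at midpoints of consecutive sorted unique risks (plus classify-
all/none); ties break toward the lowest threshold, maximizing sensitivity,
and risks equal to the cutoff classify positive.  The binary NRI between two
models is the net percentage of events moving FN→TP plus the net percentage
of non-events moving FP→TN, each model classifying at its own optimal-
accuracy cutoff (a fixed-cutoff comparison can be assembled from
`classify_at` + `compute_nri`).  Every model is compared to the baseline;
models containing the expiratory E/I index (3, 5, 6, 8) are additionally
compared to their inspiratory-only counterparts (1, 2, 4, 7) to quantify
what the expiratory acquisition adds.  Calibration is reported as an
equal-frequency binned curve (default 10 bins, sizes differing by ≤1).

**Symptom strata.**  The discrimination analysis is repeated inside the
symptomatic and asymptomatic subgroups as per-stratum refits with apparent
C and DeLong CI; no per-stratum bootstrap is run, since the stratum tables
report discrimination only.

## Synthetic data

**Phantoms.**  A rectangular lung of uniform attenuation per phase
(inspiratory default −860 HU, expiratory −720 HU; expiration must not make
the lung more lucent), into which straight cylindrical airways (lumen
−1000 HU, wall 0 HU) are rasterized with 3³-fold supersampled partial-volume
fractions — graded boundary voxels emulate CT partial-volume averaging and
keep sub-voxel boundary detection unbiased, where a hard-edged rasterization
would push boundaries outward on convex surfaces.  Emphysema is modelled as
spheres (default radius 3 mm) placed by seeded rejection sampling inside the
lung mask and trimmed so the affected voxel count matches the requested
fraction exactly (to one voxel); emphysema voxels are set to −1000 HU in the
inspiratory phase.  Noise is additive, independent, Gaussian per voxel.
Ground truth (lung mask, exact emphysema fraction, per-phase MLD, per-tube
Pi = 2πr and WA = π((r+t)²−r²), centerline polylines) is recorded from the
closed forms at build time.  Both phases share one grid: no deformation,
registration, texture or scanner-kernel simulation is attempted.

**Cohorts.**  Covariates and biomarkers are drawn from marginal
distributions matched to a male heavy-smoker screening population: age
N(62.5, 5.2²) truncated to [50, 75]; BMI N(27.1, 3.6²) truncated to
[15, 50]; current-smoker probability 0.534; pack-years log-normal with
median 38 and IQR 28–49, truncated at the 16.5 pack-year inclusion
criterion; ln IN₋₉₅₀ ~ N(ln 0.75, 0.96²); E/I ~ N(0.84, 0.059²); Pi10 ~
N(2.41, 0.51²).  COPD is then drawn from a **forward** logistic model with
configurable coefficients.  A conditional construction (biomarkers drawn
given COPD status) was rejected because it does not make the generating
coefficients the truth of the forward regression, which the
parameter-recovery check requires.  Default coefficients were fixed once so
that the full model's true-risk discrimination is ≈0.88 and the
demographics-only model's ≈0.63 at 38.3% prevalence — the regime of interest
for the diagnostic question; the intercept (−24.97) was calibrated by
simulation at n=10⁶ and frozen.  Spirometry is generated conditional on the
label and a severity draw (mild/moderate/severe = 63.4/30.9/5.7% of COPD),
so the spirometric rule reproduces the label exactly.  Symptomatic status is
independent Bernoulli(0.45) — symptom prevalence is not pinned by published
summaries, and 0.45 is a realistic screening figure; covariates are mutually
independent by default, which real cohorts (age×pack-years correlation) are
not.  Everything above is configurable per field in `CohortConfig`.

Passing tests on these cohorts therefore establish the *statistical
machinery* — estimator correctness, optimism correction, reclassification
arithmetic, parameter recovery — not agreement with any particular clinical
cohort's coefficients, C-statistics or subject-level NRIs, which depend on
unavailable subject-level data.

## Problem sizes and numerical choices

Test phantoms use 0.4–0.5 mm voxels on grids of ≤135³ voxels and the cohort
analyses use n = 1140 (study-sized), n = 5000 (moment checks) and n = 20000
(parameter recovery); the bootstrap default is B = 500 with B reduced in
smoke tests.  Degenerate inputs raise typed errors rather than silently
propagating: empty masks, single-class outcomes, constant perimeters,
in-wall seed points, missing covariates.  All randomness flows through
`numpy.random.default_rng` seeds; identical seeds give byte-identical
cohorts, phantoms and ladder reports.

## Known limitations

* Phantom airways are straight, circular and noise-free unless configured
  otherwise; wall-detection accuracy on oblique, elliptic or noisy airways
  is bounded by the tilt test (≤5°) and not characterized beyond it.
* The region-growing leak criterion uses a single global threshold schedule,
  not per-subtree optimization, so it under-segments peripheral generations
  of a deep tree.
* The FWHM wall detector is biased for walls thinner than ~2 voxels; use
  finer grids for sub-millimetre walls.
* Conditional (case/control-shifted) biomarker generation, post-
  bronchodilator definitions, decision-curve analysis and external
  validation are not implemented.
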