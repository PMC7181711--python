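# Methods

## Scope

`dceus` implements quantitative analysis of 3D dynamic contrast-enhanced
ultrasound (DCE-US) bolus data for tumor treatment-response assessment:
voxel-wise lognormal modelling of contrast time–intensity curves (TICs)
into eight volumetric perfusion maps, a fixed 1128-element radiomic
feature catalog, test–retest/treatment-sensitivity feature selection,
PCA-LDA and elastic-net classifiers of treatment response, Spearman
correlation of imaging biomarkers against microvessel density (MVD), and a
synthetic 4D cohort generator that provides ground truth for every stage.
Acquisition (scanner control, contrast injection, manual tumor
contouring) is outside scope: the package consumes 4D NIfTI volumes with
frame timestamps and 3D VOI masks.

## The bolus model

A microbubble bolus transiting a tissue bed produces a TIC modelled as an
area-scaled, time-shifted lognormal:

I(t) = AUC / (σ √(2π) (t − t₀)) · exp(−(ln(t − t₀) − μ)² / (2σ²)),  t > t₀

with I(t) = 0 for t ≤ t₀.  Parameters: AUC (a.u.·s, area under the curve),
μ (log-seconds) and σ (> 0, dimensionless) the lognormal shape, t₀ (s) the
bolus arrival time.  Derived read-outs, in closed form:

* TP = t₀ + exp(μ − σ²) — time to peak (the lognormal mode);
* MTT = exp(μ + σ²/2) — mean transit time, measured from t₀ (the
  lognormal mean); an FWHM-based MTT convention also exists in the
  field — the lognormal-mean convention is the one fixed here;
* PE = I(TP) — peak enhancement.

The closed forms are verified in the test suite against grid-argmax,
numeric-moment and numeric-integration oracles.

## Fitting

Nonlinear least squares per curve.  The engine is a batched, damped
Gauss–Newton (Levenberg–Marquardt) written directly in numpy so thousands
of voxel curves fit simultaneously on one CPU; it is free of randomness
and independent of batch composition, which is what makes the voxel-wise
maps bit-identical for any worker count.  `scipy.optimize.least_squares`
(TRF, bounded) is available for single curves and serves as an
independent cross-check in the tests, where the engine must reach the
scipy optimum's residual within 5%.

Numerical choices:

* baseline: the pre-arrival median (frames before the curve first exceeds
  10% of its maximum) is subtracted; no offset term is fitted by default;
* initialization: t₀ from the last sample before that 10% crossing
  (pulled earlier by a quarter frame); μ, σ, AUC from a signal-weighted
  quadratic regression of ln(I·τ) on ln τ, which is exact for noiseless
  model curves; trapezoid area as the AUC start value;
* bounds: σ ∈ [0.05, 3], t₀ ∈ [0, t_max/2], AUC ≥ 0 — the physiologic
  regime;
* convergence: per-curve damping adaptation; a curve leaves the active
  set when its relative SSE improvement falls below 1e-10 or damping
  saturates; `max_iter` defaults to 60 (reduced-scale studies use 8,
  which the recovery tests show costs < 1% accuracy at 5% noise);
* a voxel counts as fitted only if r² ≥ 0.25 (tunable).  This floor is
  what flags necrotic, noise-only voxels as missing rather than letting
  them pollute the maps.  Flat or all-zero curves return
  `converged=False`, never an exception;
* unfittable voxels are NaN in the maps, not zero, so histogram features
  are not biased by fill values.

## Maps

Per dataset, inside the VOI: five tracer maps (PE, AUC, TP, MTT, T0) from
the voxel-wise fits, three temporal intensity projections (MaxIP, AvgIP,
StdIP; StdIP is the population standard deviation over frames).  Arrays
are (t, z, y, x) internally; NIfTI-1 persistence transposes to the
conventional (x, y, z) order with the affine built from the voxel
spacing, and a JSON sidecar carries provenance.  Voxels are fitted in
fixed chunks of 2048 so the chunk boundaries — and hence the
floating-point results — never depend on the parallelism degree.

## Feature catalog (1128)

For each of the 8 maps, 140 features:

* 20 first-order statistics of the finite in-mask voxels: mean, std,
  variance (population), skewness, excess kurtosis, min, max, range,
  percentiles 5/10/25/50/75/90/95 (linear interpolation), IQR, entropy
  (bits) and uniformity on the 32-bin equal-width histogram normalized to
  sum 1, energy (sum of squared intensities), coefficient of variation.
* 78 direction-specific co-occurrence features: 6 GLCM properties
  (contrast, dissimilarity, homogeneity, energy = Σp², correlation,
  entropy) × the 13 unique 3D direction offsets at distance 1.
* 42 direction-averaged co-occurrence features: the same 6 properties on
  the mean of the 13 direction GLCMs at distances 1–7.

Plus the 8 ROI-level conventional bolus parameters (PE, AUC, TP, MTT, T0,
μ, σ, r²) from the lognormal fit of the VOI-averaged TIC: 8 × 140 + 8 =
1128, a fixed order shared by every table.

Maps are quantized to 32 grey levels by per-map min–max equal-width
binning (parametric maps carry no absolute scale; this also makes texture
features invariant to positive affine rescaling, e.g. injection-dose
differences).  GLCMs are symmetrized and normalized to sum 1; correlation
is undefined (missing) when a marginal variance is zero.  A 2D GLCM
implementation exists in scikit-image but not a 3D one, so the 3D matrix
is computed here and checked against a brute-force triple-loop oracle in
the tests.

The exact composition of the catalog (20 + 120 per map, plus the ROI
block) is this package's fixed, documented convention chosen so the full
surface is reproducible; it is stated prominently because other
reasonable compositions of the same total exist.

Longitudinal analysis uses percent change from the pre-treatment
baseline: 100·(v_day − v_day0)/v_day0, with zero baselines giving missing
values and baseline rows removed.

## Feature selection

A feature is retained iff

1. ICC > 0.8 on the test–retest cohort — two-way, absolute-agreement,
   single-measurement ICC(A,1) from the ANOVA mean squares, computed on
   log-transformed values (log(x − min + ε) when values are nonpositive,
   as percent changes can be); the implementation returns the ANOVA
   components for audit and is cross-checked against
   `pingouin.intraclass_corr`;
2. two-sided Wilcoxon rank-sum p < 0.05 for treated vs control in the
   treatment-responsive line at **each** post-baseline day (a config
   switch relaxes this to *any* day; the stricter per-day reading is the
   default);
3. rank-sum p > 0.1 for treated vs control in the treatment-resistant
   line at every day.

Rank-sum p-values use exact enumeration when the smaller group has ≤ 8
observations and no ties, otherwise the normal approximation with tie and
continuity corrections; completely tied data gives p = 1.  No
multiple-testing correction is applied, mirroring the stated thresholds;
a Benjamini–Hochberg option exists but is off by default.  Selection is
monotone in the thresholds and every feature appears in the audit table
with its criterion values or explicit missing flags.

## Classifiers

Positive class: treated responder; negatives: all controls and the whole
resistant line.  PCA-LDA models operate on the *selected* features
(selection precedes the PCA), z-scored, reduced to the top 16 (PCA-LDA1)
or top 2 (PCA-LDA2) principal components, then Fisher LDA.  PCA uses the
full SVD with a fixed sign convention (largest-magnitude loading
positive) for cross-platform reproducibility.  ROI-LDA and the
single-parameter LDAs use the conventional ROI parameters (PE, AUC, TP,
MTT), combined or singly.  Missing values are imputed by the
training-fold median; imputation, scaling and PCA are refit inside every
CV training fold, so held-out rows never influence preprocessing.

The elastic net is a glmnet-style penalized logistic regression:
penalty λ(α‖β‖₁ + (1−α)/2‖β‖₂²) on standardized features, a log-spaced
λ path from λ_max (KKT all-zero point) down by a factor of 100, warm
starts down the path, and λ chosen at minimum mean 10-fold CV binomial
deviance (not the 1-SE rule).  α ∈ {0.3, 0.5, 0.7} by default.  Each
individual fit is scikit-learn's saga solver; the path/CV-deviance logic
is this package's.  Per its study design, the elastic net receives the
full 1128-feature table and is evaluated on the held-out test cohort
(no outer CV).  Coefficients are reported on the original feature scale;
nonzero coefficients are the selected features.

Evaluation: stratified 10-fold CV, out-of-fold decision scores pooled
into a single empirical ROC; AUC is the midrank Mann–Whitney statistic
(verified against an O(n²) pair-counting oracle) and the 95% CI uses the
DeLong placement-value variance.  Spearman correlation to MVD uses
midranks with an exact permutation p-value for n ≤ 9.  The two-sample
power calculation offers the exact noncentral-t route (statsmodels), the
normal approximation, and a vectorized simulation; at n = 10/group,
effect 1.5 SD, two-sided α = 0.05 these give 0.887 / 0.918 / ≈ 0.89 —
the "90% power" design point.

## The synthetic cohort generator

The generator emulates a longitudinal anti-angiogenic treatment study and
its defaults are the study conditions used throughout the tests:

* geometry: 32³ voxels at 0.5 mm (tests use a reduced 16³ where noted),
  ellipsoidal VOI with semi-axes 0.38 of the grid;
* truth fields: AUC ∈ [30, 100] a.u.·s (times a per-tumor lognormal
  scale, sdlog 0.25, giving realistic between-tumor spread), μ ∈ [1.8,
  2.5] log-s, σ ∈ [0.3, 0.7], t₀ ∈ [4, 7] s.  Fields are
  Gaussian-smoothed white noise with correlation length 4 voxels,
  normalized by the theoretical smoothed-noise standard deviation at the
  reference length so that larger correlation lengths genuinely flatten
  the fields.  The arrival-time dispersion across voxels is deliberately
  narrow; real dispersion is not well characterized;
* acquisition: 2 Hz × 180 s (within the 1–5 Hz regime of 3D contrast
  imaging; reduced-scale studies use 1 Hz × 90 s); additive Gaussian
  voxel noise with σ = 5% of the local PE plus a floor at 2% of the
  median PE, clipped at zero; an optional multiplicative-gamma speckle
  surrogate; and a per-acquisition lognormal injection scale jitter
  (sdlog 0.25, the typical bolus-to-bolus repeatability of uncalibrated
  DCE-US).  The jitter is what makes ROI-averaged AUC/PE noisy across
  visits while scale-invariant map features stay stable — the mechanism
  the selection stage is designed to exploit;
* cohorts: A (responsive line, treated + control, days 0/1/3/7/10),
  B (resistant line, same design), C (2n subjects, two same-session bolus
  replicates: identical truth, independent noise and jitter),
  D (day 0/1 test cohort with MVD ground truth);
* treatment: from day 1 the treated responders' AUC field is multiplied
  by (1 − e·w)ᵏ, with e the responder effect (default 0.4), k the index
  of the post-baseline scan, and w a rim weighting from 0.5 (core) to
  1.0 (boundary) — anti-angiogenic therapy preferentially prunes the
  small peripheral vessels.  From the third post-baseline scan a growing
  core fraction (10% per scan by default) of responding treated tumors
  becomes necrotic (zero perfusion);  the resistant line and the controls
  keep their perfused core;
* histology: MVD_truth = mean in-mask AUC + Gaussian noise (SD 8 a.u.),
  recomputed from the day-1 field for cohort D so treatment effects
  propagate to the histology ground truth.

Everything is a pure function of the cohort spec: per-dataset random
streams derive from `numpy.random.SeedSequence([seed, cohort, subject,
day, replicate, ...])`, so reruns are byte-identical and replicates share
truth but not noise.

What the generator does **not** emulate: acoustic wave propagation and
speckle statistics, motion, attenuation and shadowing, nonlinear
microbubble responses, scanner log-compression, or irregular frame
timing.  Passing tests therefore demonstrate the correctness and the
statistical behavior of the computational pipeline under a faithful
kinetic model of bolus transit — not performance on real scanner data.

## Problem sizes used in the shipped studies

The test suite and the acceptance script run the full study at a reduced
scale chosen as the package's standard desk-scale validation setting:
16³ voxels, 1 Hz × 90 s, n = 10 per group, all five default days,
fit `max_iter = 8`; 20 independent study seeds in the suite's
discrimination check and 10 in the acceptance script's summary medians.
Monte-Carlo checks use 1000 fit-recovery curves, 10⁴ rank-sum null
replicates, 200 null-ICC replicates, 100 label permutations and 50
selection seeds.

## Known limitations

* The real animal and patient data behind the original study design are
  not available; reported discrimination numbers describe the synthetic
  regime only, and the headline checks are therefore directional
  (PCA-LDA above ROI-LDA) rather than value-matching.
* The MTT convention (lognormal mean) and the exact catalog composition
  are fixed conventions of this package; other conventions exist.
* The lognormal model has no recirculation term; long acquisitions of
  real data may need one.
* The elastic-net λ path uses warm-started saga fits with a capped
  iteration count; coefficients near the small-λ end of the path are
  approximate (the CV-deviance minimum is rarely there).
* ICC under the log-shift fallback (needed for negative percent changes)
  compresses large negative excursions; this is documented behavior, not
  the classical log-normal ICC.
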