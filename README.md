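# dceus — 3D contrast-ultrasound tumor perfusion quantification

`dceus` turns 4D dynamic contrast-enhanced ultrasound (DCE-US) bolus
recordings of tumors into quantitative treatment-response biomarkers.  It
is aimed at preclinical and translational imaging groups who acquire 3D
contrast-mode loops with a volume-of-interest (VOI) mask and want to go
beyond ROI-averaged bolus parameters: the package builds volumetric
perfusion maps, mines them for histogram and texture features, selects
the features that are both repeatable and treatment-sensitive, and trains
linear classifiers that separate responding from non-responding tumors.

## The method

1. **Voxel-wise bolus modelling.**  Every voxel's time–intensity curve
   I(t) is fit by nonlinear least squares with the shifted lognormal
   bolus model

   I(t) = AUC / (σ√(2π)(t−t₀)) · exp(−(ln(t−t₀)−μ)² / 2σ²),   t > t₀,

   giving peak enhancement PE, area under the curve AUC, time to peak
   TP = t₀ + e^(μ−σ²), mean transit time MTT = e^(μ+σ²/2), and bolus
   arrival time T0 per voxel.  Together with three temporal intensity
   projections (maximum, average, standard deviation) this yields 8
   aligned 3D perfusion maps per dataset, persisted as NIfTI-1.
2. **Radiomic features.**  From each map, 20 first-order statistics and
   120 3D grey-level co-occurrence (GLCM) texture features inside the
   VOI; with the 8 ROI-averaged conventional bolus parameters the fixed
   catalog holds 8×140 + 8 = **1128 features** per dataset, expressed
   longitudinally as percent change from the pre-treatment baseline.
3. **Statistical feature selection.**  Keep a feature iff it is
   repeatable on same-session test–retest bolus pairs (ICC > 0.8,
   two-way absolute-agreement single-measure), separates treated from
   control animals in a treatment-responsive tumor line (rank-sum
   p < 0.05 at each post-treatment day), and does **not** separate the
   arms in a treatment-resistant line (p > 0.1).
4. **Classification.**  On the selected features: z-score → PCA → Fisher
   LDA using the top 16 (PCA-LDA1) or top 2 (PCA-LDA2) components,
   against an LDA on the four conventional ROI parameters (ROI-LDA) and a
   glmnet-style elastic-net logistic regression (α ∈ {0.3, 0.5, 0.7},
   λ by minimum 10-fold CV deviance) on the full table.  Evaluation uses
   stratified 10-fold cross-validation with pooled out-of-fold scores;
   ROC-AUC confidence intervals use the DeLong variance.  Biomarkers are
   additionally correlated (Spearman) against microvessel density.

Because no public 4D DCE-US data exist, the package ships a first-class
synthetic cohort generator (`dceus.synth`) that emulates the full study
design — heterogeneous lognormal perfusion, rim-weighted anti-angiogenic
treatment effects, longitudinal core necrosis, test–retest bolus pairs
with injection-scale jitter, and histology ground truth — with exact
voxel-level truth for validation.  See `docs/methods.md` for the model
details and every numerical convention.

## Worked example

Fit one noisy curve (true parameters AUC = 80, μ = 2.1, σ = 0.45,
t₀ = 5 s, sampled at 2 Hz for 120 s with 5%-of-peak Gaussian noise):

```python
import numpy as np
from dceus import TimeIntensityCurve, fit_tic, lognormal_model

t = np.arange(0, 120, 0.5)
rng = np.random.default_rng(0)
clean = lognormal_model(t, 80.0, 2.1, 0.45, 5.0)
noisy = np.maximum(clean + rng.normal(0, 0.05 * clean.max(), t.size), 0)
fit = fit_tic(TimeIntensityCurve(t, noisy))
print(f"PE  = {fit.pe:6.2f} a.u.")
print(f"AUC = {fit.auc:6.1f} a.u.*s")
print(f"TP  = {fit.tp:6.2f} s")
print(f"MTT = {fit.mtt:6.2f} s")
print(f"r2  = {fit.r2:.4f}  converged = {fit.converged}")
```

prints

```
PE  =   9.62 a.u.
AUC =   83.5 a.u.*s
TP  =  11.40 s
MTT =   8.40 s
r2  = 0.9725  converged = True
```

AUC is recovered within ~4% and TP within ~2% of the truth (TP_true =
11.67 s); at this noise level t₀ and μ trade off slightly, which is why
MTT (true 9.05 s) is the least precise read-out — the Monte-Carlo
characterization in the test suite quantifies exactly this (median
errors ≈ 2% for AUC/PE, ≈ 3% for MTT over 1000 curves).

The same engine scales to whole volumes and cohorts:

```python
from dceus import CohortSpec, generate_cohorts, fit_voxelwise

spec = CohortSpec(n_per_group=10)          # the default study design
cohorts = generate_cohorts(spec)
ds = next(cohorts.datasets("A"))           # one 4D acquisition
tracer_maps, r2_map = fit_voxelwise(ds.volume4d, ds.mask,
                                    ds.frame_times_s, workers=4)
```

or from the shell:

```bash
dceus simulate --out study/ --seed 1
dceus fit-maps --volume study/A_A01_d0_r1_vol.nii.gz \
               --mask study/A_A01_d0_r1_mask.nii.gz \
               --times study/A_A01_d0_r1_times.json --out maps/ --workers 4
dceus extract-features --maps maps/ --volume study/A_A01_d0_r1_vol.nii.gz \
               --times study/A_A01_d0_r1_times.json --out features.csv
dceus run-all --out run/ --seed 1          # the whole pipeline
```

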