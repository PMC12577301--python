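# Methods

This note documents the models and procedures `fogpet` implements, the
parameters that matter, the design decisions that were genuinely open, and
what the synthetic cohorts do and do not establish.

## Synthetic cohort model

A subject's raw image on grid `G` (default 32^3 voxels of 4 mm; an
ellipsoidal brain mask with semi-axes 12/14/12 voxels) is

```
I_s(v) = c_s * ( B(v) + sum_j 1[v in R_j, group(s) = g_j] * f_j * B(v) ) + e_s(v)
```

* `B` — baseline uptake: a smooth radial gradient, 100 (arbitrary units) at
  the mask center falling quadratically to 60 at the mask edge. A non-flat
  baseline is deliberate: it makes global-mean normalization a non-trivial
  operation whose bugs planted-effect tests would catch.
* `c_s` — per-subject global multiplier, log-normal with log-scale SD 0.1
  (default). It emulates dose/habitus uptake variability and must cancel
  exactly under global-mean normalization; tests rely on that cancellation.
* `R_j, f_j` — spherical regions with signed effect fractions (e.g. +0.20 =
  20% hypermetabolism for the assigned group). Regions must lie fully inside
  the mask; violations are configuration errors.
* `e_s` — white Gaussian voxel noise, SD `noise_sd`, added inside the mask.

**Noise calibration.** Effect detectability is controlled through the
post-pipeline voxel-wise Cohen's d rather than the raw noise SD.
`calibrate_noise_sd` computes, on noiseless prototypes pushed through the
actual normalization and smoothing code, the realized in-region mean
difference, and divides by the smoothing shrinkage factor
`kappa = sqrt(sum of squared kernel weights)` (evaluated numerically from an
impulse) to find the white-noise SD giving a requested d. The package
default (`noise_sd = 39.4`) is the d ~ 1.5 calibration for the reference
+15% sphere under 10-mm smoothing.

**Clinical coupling.** UPDRS-III and LEDD are drawn group-dependently
(means/SDs chosen to match the demographics of the cohort this design
emulates: UPDRS-III 21.7 +/- 9.8 for PD-FOG vs 13.4 +/- 8.3 for PD-NFOG;
LEDD 321 +/- 217 vs 136 +/- 181 mg; HC small/zero), clipped at 0. FOG-Q is
a linear function of the subject's *realized* (noisy, scale-free) regional
means plus covariate terms and Gaussian noise, clipped to the instrument
range [0, 24] and forced to 0 for HC. Because the covariates differ by group
and FOG-Q loads on them, disease severity genuinely confounds the
region-score association — which is what the partial-correlation stage must
remove. Direct low-dimensional simulators (`simulate_partial_corr_draw`,
`simulate_confounded_draw`) construct draws whose *population* partial
correlation is exactly a requested value, for calibration-style tests.

**What the generator does not emulate:** anatomy, partial-volume effects,
scanner physics, attenuation/scatter, spatial normalization error, or
realistic spatial autocorrelation of PET reconstruction noise (smoothness
enters only through the analysis filter). Passing tests therefore establish
the *statistical* correctness of the pipeline under its stated model, not
clinical performance on real scans.

## Preprocessing

Normalization divides by the within-mask mean and multiplies by a target
constant (default 1.0; any positive constant cancels in t statistics), then
zeroes out-of-mask voxels; it is idempotent and errors on zero/non-finite
means. Smoothing is separable Gaussian, isotropic in mm
(`sigma_axis = fwhm / (voxel_size_axis * 2 sqrt(2 ln 2))`), zero-padded at
the grid boundary, with the mask re-applied afterwards; FWHM 0 is the
identity. Normalization precedes smoothing.

## Voxel statistics

Two-group contrasts use the pooled-variance two-sample t per voxel,
df = n_A + n_B - 2. Voxels with zero pooled variance are removed from the
analysis mask (their count is reported), mirroring implicit-mask behavior.
Gaussianization maps t through the exact Student-t CDF to a standard-normal
quantile using tail-symmetric survival functions, so |t| of 40 and beyond
converts without overflow or cancellation. Thresholding is one-sided at a
voxel p (default 0.001), components are labeled under configurable
connectivity (6/18/26; default 26), and components smaller than the extent
threshold are discarded. The extent rule is `size >= k` with k = 25 by
default. Increases and decreases are run as two one-sided contrasts. No
covariates enter the voxel model, and no random-field FWE correction is
applied (the thresholding regime is the uncorrected-p + extent convention).

## ROI partial correlation

ROIs are the surviving clusters; the ROI value is the arithmetic mean of the
subject's normalized uptake over the cluster's voxels. The partial
correlation residualizes both variables on [1, covariates] by least squares
and correlates the residuals; significance is a two-tailed t test with
df = n - 2 - k. Correlations pool the two PD groups (n = 29 by default); HC
subjects are excluded (their FOG-Q is structurally 0). FDR control is
Benjamini-Hochberg step-up (via statsmodels) across ROIs at alpha = 0.05;
adjusted p-values are the monotonized `min(m p_(i) / i, 1)`.

## The volumetric CNN

Architecture: three conv(3x3x3, stride 1, same padding) + ReLU +
maxpool(2x2x2, stride 2) blocks with 16, 32, 64 output channels; flatten;
FC to 128 + ReLU; head of 2 log-softmax outputs (classification, NLL loss)
or 1 linear unit (regression, squared-error loss). Same padding makes three
poolings map each spatial dim D to D/8, so the flatten length is
64 * prod(D_i/8) — 32768 for 64^3 inputs, 4096 for 32^3. Input dims must be
multiples of 8.

Training: Adam with lr 3e-3, weight decay 2e-3 applied the coupled way
(added to the gradient, as in classic `Adam(weight_decay=...)`), batch 16
for training, batch 1 at test time, up to 300 epochs, early stopping when
validation accuracy (validation MSE for regression) has not improved for
100 consecutive epochs. The selected model is the validation-best epoch,
earliest on ties. Because selection keeps the *first* best, once validation
accuracy reaches 1.0 no later epoch can change the selected model, so
training halts there; this shortcut is result-identical and can be disabled
(`stop_when_perfect=False`).

Numerical/initialization choices (ours; they affect optimization speed, not
the hypothesis class):

* **Implementation** — conv/pool/FC layers are written in numpy with
  explicit backpropagation; convolution is an im2col gather plus one BLAS
  matrix multiply per batch; pooling routes gradients to the first maximal
  element per window (gradient conserved under ties). Gradients are verified
  against finite differences and the forward pass against an independent
  scipy correlation oracle.
* **Initialization** — He-uniform (bound sqrt(6/fan_in)) for the conv
  stack; the FC representation layer uses twice that gain and the output
  head is initialized near zero with zero bias. Deep ReLU stacks under
  coupled weight decay otherwise die toward constant outputs at these
  hyperparameters; the near-zero head starts optimization at the
  class-prior loss.
* **Input scaling** — inputs are standardized per voxel with training-set
  statistics inside the model wrapper (zero-variance voxels, i.e. everything
  outside the mask, stay 0). Regression targets are standardized during
  optimization and predictions mapped back, so the zero-initialized head
  starts at the training-mean prediction.
* All randomness (init, shuffling, splits) flows from explicit integer
  seeds; training is bit-reproducible for a fixed seed.

Baselines: MLP (one hidden layer of 128, scikit-learn) and RBF-SVM (C = 1)
on volumes block-averaged to 16^3 and flattened; a 2D CNN (two conv-pool
blocks, 16/32 channels) on the central axial slice; polynomial (default
degree 2), decision-tree and random-forest regressors on ROI-mean feature
vectors. All sit behind one fit/predict contract so the CV harness is
model-agnostic.

## Cross-validation and metrics

Subjects are shuffled once per run seed and split into k = 10 contiguous
folds (sizes differing by at most 1). Per fold, the nine training folds are
split 80/20 into train/validation, stratified by class when each class has
at least two members (reduces degenerate validation sets at n ~ 29).
Classification metrics are computed from confusion counts and reported in
percent; undefined precision/recall in a degenerate fold is reported as
missing (NaN) with a warning and excluded from the mean, never silently
zeroed. Aggregation is mean +/- sample (n-1) SD across folds. All test-fold
scores are concatenated into one global ROC; if the raw AUC is below 0.5 the
reported value is 1 - AUC with `inversion_applied` set, so reported AUC is
always >= 0.5. Regression reports per-fold MSE/MAE/RMSE (RMSE_f =
sqrt(MSE_f) by construction).

Task definitions: `pd_vs_hc` uses all 46 subjects with PD = FOG + NFOG as
the positive class; `fog_vs_nfog` and `fogq_regress` use the 29 PD subjects,
with PD-FOG positive. The positive class for precision/recall is the
disease/FOG class.

## Orchestration

`RunConfig` (YAML, strict keys, defaults = the reference protocol values:
fwhm 10 mm, p 0.001, extent 25, lr 3e-3, wd 2e-3, k = 10) drives
`run_all`, which executes simulate -> preprocess -> voxelstats -> roicorr ->
evaluate, writing NIfTI maps, TSV tables, JSON reports, and a manifest with
per-file SHA-256 digests, the config hash, and the per-stage seeds fanned
out of the run seed via `numpy.random.SeedSequence.spawn`. Stage failures
abort with the stage name; completed outputs are preserved.

## Test and acceptance problem sizes

Statistical checks run at deliberately compact sizes chosen to keep the
suite fast while leaving the assertions well-powered: 32^3 grids with 4-mm
voxels, 15 subjects per group for error-calibration and recovery runs
(20 replicates each), 200 draws for coverage checks, and 46-subject cohorts
for the cross-validated CNN runs (five CV seeds). The "strongly separated"
CNN condition plants a dense 16-sphere pattern (|effect| 35%, radius 2.5
voxels, off the central slice) with noise calibrated to voxel-wise d ~ 2;
the model-family comparison uses a sparser 12-sphere variant at radius 2,
where slice-based and block-averaged baselines lose most of the signal, and
runs five seeded splits as a reduced-scale stand-in for the full
cross-validated comparison.

## Known limitations

* The voxel model is a plain two-group t contrast; ANCOVA-style covariate
  adjustment at the voxel level is out of scope.
* Cluster peaks are reported in world mm of the synthetic affine; no
  anatomical atlas lookup is attempted.
* The 2D-CNN baseline sees only the central axial slice; other slicing
  strategies would give it more signal.
* Monte-Carlo acceptance checks are seeded and use fixed replicate counts;
  they bound error rates statistically, not deterministically.
* Whether the smoothing filter of the emulated protocol was isotropic in mm
  or in voxels is not determinable from its description; isotropic-in-mm is
  assumed (the common convention).
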