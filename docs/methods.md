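# Methods

## The prediction problem

STAS (spread through air spaces) is a binary, surgically adjudicated
label. The pipeline's premise is that STAS-positive nodules differ from
negative ones in their *growth dynamics* between two pre-surgical CT
scans — faster and more anisotropic volume growth and drifting internal
heterogeneity — and that two complementary encodings of those dynamics,
per-feature time slopes and CNN features of registration-subtracted
difference images, improve on single-scan ("classic") features.

## Synthetic scan pairs

The phantom renders an ellipsoidal nodule (≈ −50 HU) in aerated-lung
background (−800 HU) with a rigid high-attenuation spine block (+300 HU).
Per axis *i*, the semi-axis evolves exponentially,
r_i(t) = r_i0 · exp(g_i t) (a linear mode exists behind a flag); intra-
nodule heterogeneity is a smooth random field expressed in the nodule's
local frame so it translates, rotates and scales with the nodule; its
standard deviation may drift between scans. The whole follow-up scene
(nodule *and* spine) undergoes a rigid motion (3 translations, in-plane
rotation), and each scan receives independent additive Gaussian noise.
Masks are always the analytic ellipsoid, never a segmentation of the
rendered intensities, so ground truth is exact and non-circular.

Defaults (one 64³ grid at 1 mm isotropic): baseline radius 5–8 mm,
texture SD 20 HU, noise SD 5 HU, motion SD 2 mm / 2°, intervals 30–120
days. Class recipes:

* **default** — negatives grow isotropically at 0–0.001/day (volume
  doubling time ≳ 300 d); positives at 0.002–0.005/day with anisotropy
  (1.4, 1.0, 0.7) and heterogeneity drift 0.15 HU/day. These rates mirror
  indolent vs. aggressive nodule doubling times and keep the nodule
  inside the grid at the longest interval.
* **growth_signal** — both classes isotropic, the *follow-up* radius is
  drawn from the same 6–9 mm distribution for both classes and the
  baseline radius is back-computed from the class's growth rate
  (0.0005–0.0015/day vs. 0.008–0.012/day over a fixed 90-day interval).
  Classic follow-up-only features then carry no class information by
  construction; only trajectories do. This cohort operationalizes the
  claim that delta information, not the final snapshot, separates the
  classes.

Cohorts derive per-subject seeds from one master seed and are
bit-reproducible. Default prevalence is 24.4% positive, the realistic
imbalance for this label; the separation experiments use 0.5 so both CV
folds and the CNN see enough positives at n = 200.

What the phantom does **not** emulate: ground-glass/solid composition,
vessels and bronchi entering the nodule, respiratory deformation, scanner
kernels, or slice-thickness anisotropy artifacts. Passing tests therefore
demonstrate the pipeline's mechanics and its sensitivity to growth
signal, not clinical performance on patients.

## Regions of interest

Batch refinement replaces interactive initialization: the caller provides
an initial mask (truth mask, threshold seed, or an external delineation),
a morphological Chan–Vese active contour (region-based; default 100
iterations, smoothing 1) refines it, and erode/dilate/open/close with
world-space (mm) structuring elements clean it up; opening approximates
the exclusion of thin vessels. The peritumoral region is the shell of
voxels within (0, 3] mm Euclidean distance of the tumor, spacing-aware,
always disjoint from the tumor.

## Radiomics

The engine is implemented in NumPy/SciPy and produces the standard
851-name inventory (names follow the `<filter>_<family>_<Feature>`
convention). Choices the field usually leaves implicit:

* **Discretization**: fixed bin width, 25 HU. Texture matrices use
  1-based bin indices re-based to the mask minimum.
* **Aggregation**: GLCM and GLRLM are computed per 3-D direction (the 13
  unique offsets) and features are averaged over nonempty directions;
  GLSZM zones use 26-connectivity; GLDM dependence counts equal-level
  26-neighbors with the center included (so dependence size ≥ 1);
  NGTDM uses the mean of valid in-mask 26-neighbors.
* **Shape**: mesh volume/area from marching cubes on the padded binary
  mask (no smoothing — note a voxelized sphere then caps sphericity near
  0.9); axis lengths from 4·√λ of the physical-coordinate covariance;
  diameters from boundary-voxel convex hulls.
* **Wavelet**: one-level 3-D DWT (`coif1`), each of the 8 sub-bands
  reconstructed alone back to the original grid so the original mask
  applies; the 93 non-shape features are recomputed per band.
* **Resampling**: volumes are cubic-resampled to 1 mm isotropic before
  texture extraction when the native spacing differs (configurable).
* **Normalization**: min–max with ranges fitted on the training rows
  only; held-out rows may legitimately fall outside [0, 1]; constant
  features map to 0 with a warning. Inside cross-validation this fitting
  happens per training fold.

## Delta features and ICC

Delta features are elementwise slopes in feature-units/day; time is
always days. "Classic" features come from the follow-up scan (the last
scan before surgery). The dual table is
`classic_intra | classic_peri | delta_intra | delta_peri`
with block-prefixed names, 3404 columns at the full inventory.

Reproducibility uses ICC(2,1) — two-way random effects, absolute
agreement, single measurement — computed vectorized from ANOVA mean
squares; raters are interchangeable observers, which is why the
absolute-agreement random-raters form is appropriate. A feature passes
only if *both* the intra-observer (repeats) and inter-observer (raters)
ICC exceed 0.75 (strictly greater). Degenerate all-equal tables are
perfect agreement (ICC = 1) by convention. The gate is applied to
whichever table enters selection (classic, delta, or dual); the pipeline
simulates observers by jittering the delineation radius a few percent.

## Views, registration, delta-images

For each body axis the slice with maximal in-plane mask area (lowest
index on ties) is cropped to the tight bounding square plus a 4-px
margin. Registration estimates a rigid + isotropic-scale similarity
transform of the baseline view onto the follow-up view by one of three
method classes: ORB keypoints + RANSAC, mean-squares minimization
(monomodal), or mutual-information maximization (multimodal; default).
The intensity methods use Powell's method from a phase-correlation
translation init plus rotation multistarts, with bounds that keep the
scale invertible. Two safeguards: a registration whose SSIM falls below
the untransformed pair's by more than 0.02 is replaced by identity, and
a direct result under the fallback threshold (default SSIM 0.5) or a
keypoint failure triggers the **spine fallback** — a rigid-only transform
estimated on spine-landmark crops and applied to the nodule view. Spine
crops from the two timepoints share one crop window (centered on the
fixed scan's landmark): centering each scan on its own landmark would
absorb exactly the motion being estimated.

The delta-image is follow-up minus warped baseline, clipped at ±200 HU,
mapped to [0, 1] (0.5 = no change), and resized to 64×64 (227×227
available). SSIM is the Gaussian-window (11×11, σ = 1.5, k1 = 0.01,
k2 = 0.03) formula averaged over fully-inside windows; constant pairs
score 1 by convention. Note that full intensity inversion does *not*
yield a negative score unless local means vanish — the luminance and
structure terms are both negative and multiply out positive.

## Delta-DL network

A deliberately small AlexNet-style stack implemented directly in NumPy:
three 3×3 conv blocks (8/16/32 channels, ReLU, 2×2 max-pool) on 64×64
inputs, a **linear** fully-connected feature layer of 10 units, and a
2-way softmax head — ~26k parameters. One network is shared across the
three views, with the view identity as a constant second input channel
(x → 0, y → 0.5, z → 1); per-subject features are the 3 × 10
concatenated feature-layer activations. Training is momentum SGD
(lr 0.01, momentum 0.9, batch 32, 20 epochs default) with class-weighted
cross-entropy, deterministic under a fixed seed.

The feature layer is linear rather than ReLU because a 10-unit ReLU
bottleneck can represent one class as "all units silent", which zeroes
the gradients Grad-CAM needs. Grad-CAM weights the final conv block's
channels by the spatial mean of the gradient of the *discriminative
margin* (target logit minus the mean of the others; for two classes the
logit difference), takes the ReLU'd weighted sum, upsamples to the input
size and min–max normalizes; constant maps normalize to all-zeros.

To avoid the circularity of training the CNN on the same subjects whose
features are later cross-validated, the pipeline trains the CNN on a
stratified half of the cohort and evaluates all models (classic and dual
alike) on the held-out half.

## Selection, classifiers, evaluation

The registries enumerate 45 selector and 32 classifier entries — 1440
combinations — built from ~15 selector and ~12 classifier base families
with hyperparameter variants counted as distinct, every entry functional
(filter statistics, embedded-model weights, tree importances, RFE,
ReliefF; linear/logistic models, SVMs, trees and ensembles including
XGBoost/LightGBM, kNN, discriminant analysis, naive Bayes, a small MLP).
The registry *identities* are a configurable stand-in of the stated
cardinality, not a canonical list.

Evaluation is stratified k-fold cross-validation repeated (default 40
replications; the pipeline default is smaller for desk-scale runs), with
min–max normalization and feature selection refitted inside every
training fold; the replication AUC pools out-of-fold scores, and the CI
is the percentile interval across replications. Grid cells that crash
are recorded as missing rather than failing the grid; the best cell is
the highest mean AUC.

Elastic-net selection ("LASSO, α = 0.5" read as mixing parameter 0.5;
pure L1 via `alpha=1.0`) picks the penalty at the minimum mean
cross-validated MSE and returns the nonzero-coefficient features with
the full coefficient trajectory. ReliefF uses range-normalized Manhattan
distances, K nearest hits/misses, and class-prior-weighted miss
contributions. PSM fits a logistic propensity on six shape/first-order
covariates (volume, surface area, sphericity, maximum 3-D diameter, mean
intensity, entropy — a documented stand-in), matches 1:1 without
replacement on the logit with a 0.2·SD caliper, and reports standardized
mean differences; note 1:1 matching balances the propensity score, so
per-covariate SMDs retain sampling noise of order √(2/n). Follow-up
interval groups use [21, 91), [91, 365), [365, 730) days.

## Problem sizes and tolerances

The test suite and the acceptance script run desk-scale problems chosen
as the smallest sizes at which each property is stable: 64³ phantoms,
n = 200 for the separation experiment (wavelet off there — the property
concerns the classic/delta contrast, not the wavelet block), 20 seeds
for planted-signal LASSO recovery, n = 500 for null-AUC calibration.
Oracle equivalences are exact to stated tolerances (slopes 1e−12, ICC
1e−10, SSIM 1e−8, Grad-CAM 1e−6); stochastic properties use fixed seeds.

## Known limitations

* The phantom's exponential growth is a modeling convenience; nothing in
  the pipeline assumes it, and real growth is irregular.
* 2-D view-level similarity registration cannot express anisotropic
  growth; the delta-image then shows a residual rim by design, which is
  the signal the CNN consumes, but registration SSIM is intrinsically low
  for fast-growing nodules whichever method is used.
* The ICC study uses simulated delineation jitter, not human observers.
* Clinical AUCs on patient cohorts are not reproducible here; all
  reported numbers are properties of the synthetic study conditions.
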