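# Methods

This note records the scientific and numerical choices behind
`gradiomics`: the model assumptions, the parameters that matter, what
the synthetic generator does and does not emulate, and the conventions
fixed where standard definitions leave freedom.

## Pipeline model and assumptions

The method assumes a binary image-level label (healthy = 0, lesion = 1),
a single grayscale channel, and a convolutional backbone that exposes
(i) a penultimate feature vector — pinned to the post-global-pooling,
pre-classification-head activations — and (ii) the last convolutional
layer's activations together with the gradient of a class score with
respect to them. Any model satisfying this adapter contract can drive
the pipeline; the bundled `TinyConvNet` (three 3×3 conv blocks, 2×2 max
pooling, global average pooling, dropout-0.30 two-class head) exists so
the whole method can be exercised and tested without a deep-learning
framework or pretrained weights. Its inputs are centered (x − 0.5)
before the first convolution; without centering, He-initialized
convolutions on [0, 1] images sit on a long cross-entropy plateau and
convergence becomes an accident of the seed.

Grad-CAM follows the standard formulation: channel weights are the
spatial means of the class-score gradients, the raw map is the ReLU of
the weighted activation sum. The map is min–max normalized (a constant
positive raw map becomes all ones; a non-positive one all zeros),
bilinearly upsampled to image resolution, re-normalized so its maximum
is exactly 1, and thresholded with an inclusive `>=` comparison
(default 0.5, configurable). The saliency target class defaults to the
model's prediction for the image and can be pinned to the lesion class.
Masks are always computed on the original (non-augmented) image.

Mask quality control: a mask is reliable iff its area fraction is
≥ 0.01 and the active fraction of the 1-pixel outer border is ≤ 0.30.
The border denominator is the border pixel count, which makes the rule
scale-free. Unreliable masks zero-pad the radiomic block but the image
still contributes CNN features — note that the reliability flag itself
can carry class information (attention is stronger on lesioned images),
which is a property of the method, not an artifact of this
implementation.

## Radiomics conventions

Features follow IBSI-style definitions with these fixed conventions:

* discretization: fixed bin width, default 25/255 on the [0, 1] scale
  (the common 8-bit default); `level = floor((x − min_roi)/w) + 1`;
* texture matrices: distance 1, directions {0°, 45°, 90°, 135°},
  symmetric GLCM accumulation, features computed per direction then
  averaged; GLDM uses α = 0 and the 8-neighborhood (dependence size
  = dependent-neighbor count + 1 in the feature formulas); NGTDM uses
  the 8-neighborhood and counts only pixels with ≥ 1 in-mask neighbor;
* moments use the population (divide-by-n) convention; skewness and
  kurtosis of a constant region are 0 by convention, correlation of a
  single-level GLCM is 1, NGTDM coarseness is capped at 1e6 when its
  denominator vanishes;
* shape is mesh-based: marching-squares contours at level 0.5 give the
  surface (shoelace) and perimeter; axis lengths come from 4·√λ of the
  pixel-coordinate covariance eigenvalues. A single pixel therefore has
  mesh surface 0.5 and perimeter 2√2. Marching squares on a hard binary
  disk overestimates the true perimeter by ≈ 6%, so the sphericity of a
  rasterized circle converges to ≈ 0.943 rather than 1 — a property of
  the contour rule, pinned in the tests;
* the census is fixed at 18 + 24 + 16 + 14 + 5 + 10 = 87 named features
  in a stable order; every family is validated against brute-force
  enumeration oracles on random small masked images, and every feature
  is invariant to pixels outside the mask.

## Fusion, reduction, classification

The fused vector is `[embedding | radiomics]`. Test-time augmentation
averages the embedding over a deterministic view list (identity,
horizontal flip, vertical flip, ±10° rotations — deterministic views
preferred over random draws for reproducibility); the radiomic half
always comes from the original image and its original mask. TTA applies
at inference only: in cross-validation the training folds use
identity-view features and only held-out folds are scored with
TTA-averaged features.

ANOVA-F selection computes F = MSB/MSW per feature with df (k−1, n−k);
exactly constant features get F = 0 and zero within-class variance with
non-zero between-class variance maps to a finite sentinel (1e12).
SelectKBest keeps the k (default 100) highest-F features, ties broken
toward the lower index. PCA retains the minimal component count
reaching 95% explained variance, centered on the training mean, with
each component's sign fixed so its largest-magnitude loading is
positive. Reductions are always fit inside the training folds.

Default grids: random forest n_estimators {100, 300, 500} ×
max_depth {None, 10, 20}; XGBoost learning rate {0.05, 0.1, 0.3} ×
max_depth {3, 6} × min_child_weight {1, 5} (100 trees, base_score 0.5).
Grid search selects by mean fold accuracy; ties break toward the
simpler model (fewer trees, then shallower), then grid order.

Backbone training defaults mirror the reference protocol (Adam,
lr 1e-4, early-stopping patience 10, L2 1e-4 on convolutional weights,
dropout 0.30). Desk-scale runs use lr 1e-2 with patience equal to the
epoch budget — the tiny CNN needs the larger step size to leave its
initial plateau within minutes.

## Statistics

All alternatives are two-sided. The Wilcoxon signed-rank test drops
zero differences, assigns average ranks to tied magnitudes, and for
n ≤ 25 uses the exact sign-permutation null computed by dynamic
programming (valid under ties), so five same-sign fold differences give
p = 2/32 = 0.0625 and four give 0.125. The permutation test shuffles
labels within folds and reports the plain proportion of permuted scores
≥ the observed one (p = 0 is representable; a `plus_one` switch gives
the (b+1)/(m+1) variant). McNemar uses the exact binomial two-sided p
when the discordant count is < 25, continuity-corrected chi-square
otherwise. Holm–Bonferroni is the standard step-down with monotone
adjusted p-values. AUC is the tie-aware rank statistic (Mann–Whitney U
normalized), which the tests verify against trapezoidal ROC
integration. Metrics with zero denominators are reported as NaN with an
`undefined` flag, never silently 0.

Tree-Shapley attributions use the path-dependent polynomial-time
recursion with training covers as node weights, computed in the reduced
feature space actually fed to the trees (principal components are
labeled `pc_k`, never mapped back to fabricated single-feature names;
selected features keep their fused-vector names). For forests the
explained output is the lesion probability; for XGBoost it is the
log-odds margin, evaluated in float64 over the extracted trees — the
booster's own float32 accumulation agrees to ~1e-5, and split
comparisons replicate the booster's float32 threshold semantics so
routing is identical. Local accuracy (base + Σφ = output) holds to
1e-6; a brute-force subset-enumeration oracle over the cover-weighted
value function validates the recursion on small trees to 1e-9.

## Synthetic data: what it emulates, and what it does not

Each image is a bright, tilted, elongated "root" ellipse on a mid-gray
background, overlaid with correlated clutter (Gaussian-smoothed noise,
SD 0.08, correlation length 4% of the image side) that stands in for
trabecular bone texture, plus white pixel noise (SD 0.05). Lesion-class
images darken an elliptical region at the root apex by
`lesion_contrast × severity` and raise its white-noise SD to
`background_noise_sd + severity × lesion_texture_sd`, with severity
drawn per image from U(0.3, 1.0) to emulate the mix of advanced and
early lesions in a clinical archive. Intensities are generated in
[0, 1] and quantized to 8 bits on write. One seed drives everything;
per-image substreams come from `SeedSequence(seed, spawn_key=(i,))` so
subsets are reproducible.

The effect-size defaults (contrast 0.12, texture 0.10) were chosen so
that, against the clutter, classification is good but imperfect —
accuracies in the 0.93–0.98 band, the regime real periapical reading
sits in. Without clutter every lesion is a matched-filter target
(per-lesion SNR ≈ contrast·√area/noise ≈ 12 even at contrast 0.05) and
all methods saturate at 1.000, which makes comparisons between feature
sets uninformative. These are study knobs, not clinical measurements:
no quantitative texture statistics of real lesions back them.

What the generator does **not** emulate: multi-tooth anatomy, sensor-
specific noise spectra, exposure drift between devices, label noise,
and patient-level correlation between images. Passing tests on this
synthetic data therefore demonstrate that the pipeline recovers a
planted attention-localized texture/contrast signal and that every
computational step is correct — not that the method reaches any
particular accuracy on clinical radiographs.

## Reference study sizes

The signal-recovery study (tests and `scripts/acceptance.py`) uses: a
200-image archive to train the backbone (85/15 train/val, 60 epochs,
lr 1e-2) — the backbone is a *fixed extractor* never shown the
evaluation data, mirroring the pretrained-backbone structure of the
full method and keeping the zero-effect control honest — and an
independent 300-image evaluation set at side 64, classified with a
random forest (grid {100, 300} trees × depth {None, 10}, SelectKBest
k = 100) under stratified 5-fold cross-validation. The zero-effect
control regenerates the evaluation set with contrast and texture zero
and must land inside the 95% binomial CI of 0.5. These sizes are the
package's reference desk-scale conditions; the pipeline accepts larger
ones unchanged.

## Known limitations

* The test backbone is deliberately small; its Grad-CAM maps are coarse
  (last conv at 1/4 resolution) and its embeddings cap the achievable
  ceiling on hard synthetic conditions.
* Fused-vs-ablation differences at n = 300 are a few samples; strict
  orderings between arms are reproducible for a fixed seed but not a
  stable population-level claim.
* Radiomic values depend on the discretization and angle conventions
  above; comparisons with other radiomics software require matching
  settings.
* The permutation test reruns the classifier stage only, not backbone
  training, in the scaled configurations.
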