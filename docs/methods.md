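# Methods

## Problem and model

Laparoscopic total mesorectal excision (TME) is hard in an anatomically
constrained ("difficult") pelvis — narrow inlet, deep curve — and the choice
between a transabdominal and a transanal approach benefits from knowing the
difficulty preoperatively. `pelvistrat` implements a two-stage study around
this question:

* **Stage I** compares perioperative outcomes between difficult and
  non-difficult groups to establish that the difficulty grading is clinically
  meaningful: Pearson chi-squared (no continuity correction) for 2×2
  categorical tables, pooled-variance two-sample *t* for normally summarised
  continuous variables, Mann–Whitney for skewed ones.
* **Stage II** trains a binary classifier on the *binary pelvis bone mask*
  (bilateral ilium + sacrococcyx, background 0, bone 1) fused with three
  clinical covariates (BMI, sex, neoadjuvant therapy), under stratified
  4-fold cross-validation with a fixed held-out test set, and merges the four
  fold models by averaging their prediction scores.

The classifier is a 3D residual network with ResNet-50 topology, modified for
what is fundamentally a *positional* task — the discriminative information is
the spatial arrangement (distances, gaps) of bone, not texture:

* a CBAM attention block (channel gate from global max/avg descriptors
  through a shared two-layer bottleneck, then a spatial gate from the
  channelwise max/mean maps through one odd-kernel convolution) refines the
  output of every residual block;
* all pooling layers are replaced by convolutions, and every stride-2
  convolution uses an *even* kernel (default 2), so downsampling never
  introduces a half-voxel offset;
* the global-average-pooling head is replaced by a 1×1×1 channel-shrinking
  convolution followed by stride-2 even-kernel convolutions down to spatial
  size 1×1×1, keeping positional information in the final feature vector
  (this requires the final stage's spatial size to be a power of two, which
  constrains the input side to a multiple of 16 with a power-of-two
  quotient);
* the clinical vector, min–max normalized into (0,1) with bounds estimated
  on the training split only (ε = 10⁻³ open-interval clamp), passes through a
  linear layer whose output multiplicatively re-weights the image feature
  vector; a dropout (rate 0.5) + linear classifier produces one logit, and a
  sigmoid maps it to a score in (0,1). A case is called difficult when the
  score reaches 0.5; the tie goes to difficult, the conservative call for
  surgical planning.

Training minimises the binary cross-entropy
−[y·log f(x) + (1−y)·log(1−f(x))] with AdamW (weight decay 10⁻⁸), global
gradient-norm clipping at 0.5 and batch size 4. Each epoch the training
cases are enlarged 4× by online augmentation (left–right flip with
probability 0.5; axial rotation about the inferior–superior axis, uniform in
[−5°, +5°], probability 0.4, nearest-neighbour for binary volumes). The
variants *replace* the originals within the epoch (4 variants per case, the
unaugmented original is not added; `augment_copies` is configurable).
Validation is evaluated once per epoch on the validation loss; early
stopping is armed only after a minimum-iteration floor, and the
best-validation checkpoint is returned.

Images are normalized before training: resampled to isotropic 1.5 mm voxels
(nearest-neighbour for masks so the {0,1} contract survives; an input
already on the target grid is returned unchanged), label maps binarized
(any bone label → 1), and all volumes zero-padded to a common shape with
the content centred, which keeps the rotation centre meaningful.

## Attention maps

GradCAM++ extended to 3D, from the feature map *f* and gradient map *g* of a
selected stage (gradients of the predicted-class logit; the negated logit for
a non-difficult prediction, configurable to always use the difficult class):

    α = g² / (2 g² + Σ_xyz f·g³)       (zeros in the denominator → 1)
    w_c = Σ_xyz α · ReLU(g)
    heatmap = ReLU( Σ_c w_c f_c )

The α denominator's zero-replacement follows the canonical GradCAM++ form
with the factor 2 and the division made explicit. The layer-resolution map
is upsampled trilinearly to the input grid (grid-aligned block convention;
constants are preserved and smooth mass approximately conserved) and clamped
at 0 for display. For cohort-level maps, each case is warped to a reference
(the case with median foreground count) by Demons non-rigid registration
(SimpleITK's symmetric-forces filter, 100 iterations, displacement-field
smoothing σ = 1.5 voxels; binary masks are Gaussian-presmoothed at σ = 1
voxel so boundary gradients extend into the inter-surface gap), the same
field warps the heatmap, and voxelwise means give the average skeleton and
average heatmap. The top 0.5% of heat (64 000 voxels on a 12.8 M-voxel
grid) is highlighted, ties at the cutoff broken by lexicographic voxel
index.

## Synthetic phantom cohorts

Patient MRI cannot be redistributed, so the pipeline ships a phantom
generator that preserves exactly the causal structure the method is supposed
to recover. Each phantom is a binary volume with two lateral "iliac wing"
shells whose minimal left–right separation is the *pelvic inlet width*
(narrowest at mid-height, flaring outwards above and below), plus a
posterior midline wall standing in for the sacrococcyx, all perturbed by a
smooth random surface jitter (σ ≈ 0.8 mm). Cohorts draw inlet widths from
Normal(20, 3) mm (clipped at 2.5 SD) on a 32³ grid of 1.5 mm voxels, and
covariates from the clinical cohort this pipeline targets: 68% male, 71%
neoadjuvant-treated, BMI ~ Normal(24.1, 3.4) kg/m². Labels come from a
logistic model on standardized narrowness (slope 4.0), male sex (2.0), BMI
z-score (0.6) and neoadjuvant therapy (1.2) — directions and relative
strengths mirroring the clinical contrasts (the male contrast is by far the
strongest clinically). The intercept is calibrated by bisection so the
cohort's expected difficult fraction hits a target (default 53/108 ≈ 0.491,
the enrolled-cohort fraction); an unreachable target leaves a warning in the
cohort metadata. Label noise comes solely from the logistic draw — there is
no separate label-flip noise — so parameter recovery stays interpretable;
with the default slopes the Bayes accuracy of the mechanism is ≈ 0.88.

What the phantoms deliberately do **not** model: real iliac/sacral anatomy,
soft tissue (tumor, mesorectum), scanner artefacts, segmentation error.
Passing the recovery suites therefore shows the *pipeline* can recover a
known geometry→difficulty mechanism end to end; it says nothing about
performance on real patients.

## Problem sizes and presets

Two network presets share every operator:

| preset | input | stem | stage blocks | stage widths | reduction | SA kernel | shrink |
|--------|-------|------|--------------|--------------|-----------|-----------|--------|
| desk   | 32³   | 8 (k4 s2) | 1,1,1,1 | 8,16,32,64   | 4  | 3 | 32  |
| full   | 128³  | 64 (k8 s2)| 3,4,6,3 | 256,512,1024,2048 | 16 | 7 | 256 |

The full preset keeps the published optimization settings (learning rate
10⁻⁶, ≥ 7000 iterations, batch 4). The desk preset is the package's own
laptop-scale configuration: at 32³ with a ~52 k-parameter network the
full-scale learning rate cannot move the weights in a sensible number of
iterations, so the desk settings are learning rate 10⁻³, a 200-iteration
floor, early-stop patience 3 evaluations and at most 10 epochs; any
deviation from the full-scale values is visible in the run manifest. The
desk input is 32³ rather than 48³ because the shrink head's exact-halving
chain requires a power-of-two final spatial size (48³ leaves 3³). Desk-scale
attention maps default to `layer3` (4³ resolution at 32³ input), whose
*relative* resolution matches a fourth-stage map on full-size volumes;
`layer4` (2³) is a single coarse octant grid and is available by
configuration. Recovery experiments use 120-phantom cohorts, a 25% held-out
test split and 4 folds; each end-to-end run takes roughly two minutes on one
CPU.

## Numerical and implementation choices

* The network runs on a compact NumPy reverse-mode autodiff engine written
  for this package (`pelvistrat.nn`): 3D convolution via im2col/GEMM, batch
  normalization (momentum 0.1, ε = 10⁻⁵), linear, ReLU/sigmoid, axis
  reductions, concatenation, dropout, and a numerically stable
  binary-cross-entropy-on-logits (softplus form). All operators carry
  finite-difference gradient tests. Every intermediate tensor retains its
  gradient after `backward()`, which is what GradCAM++ capture reads.
* Weight init: He-normal for convolutions, uniform ±1/√fan-in for linear
  layers; BatchNorm starts at identity.
* All randomness flows through seeded `numpy` generators; module boundaries
  use keyed seed sequences so two components given the same integer seed
  never replay the same stream. Fixed seeds reproduce cohorts, training
  histories and metrics bit-for-bit.
* Metric conventions: positives = difficult; metrics with zero denominators
  are reported as absent, never 0; presentation rounding is half-away-from-
  zero at 3 decimals (as clinical tables print). AUC uses the trapezoidal /
  rank (Mann–Whitney) convention, AP the non-interpolated step sum — both
  via scikit-learn behind the package's metric surface.
* Stage-I test choices: chi-squared without Yates correction (the printed
  stoma/neoadjuvant p-values match the uncorrected form; corrected values do
  not), pooled-variance *t* from summary statistics (matches the printed BMI
  p-value), Mann–Whitney exact for tie-free samples with ≤ 8 per group and
  tie-corrected normal approximation otherwise. Fisher's exact test is
  available for sparse tables — the printed anastomotic-leak p-value (0.043)
  matches Fisher, not Pearson, so that row is treated as Fisher-tested.
* The confusion-matrix auditor enumerates all integer (TP, FP, TN, FN)
  decompositions of n (pruned by the recall/precision rounding windows) and
  returns every matrix whose rounded metrics match; on the published merged
  row (n=25) the solution is unique.

## Known limitations

* The phantom geometry is stylised; localization results (the inlet-band
  fraction) depend on the phantom's regular structure and the coarse CAM
  grid, and are reported as a stochastic majority-of-seeds property, not a
  per-seed guarantee.
* The full-scale preset is provided and validated structurally (block
  counts, attention placement, no pooling), but its published clinical
  performance cannot be reproduced here because the patient MRI data are not
  deposited.
* Demons registration is intensity-driven on presmoothed binary masks; for
  wildly non-overlapping shapes it only improves, not guarantees, overlap.
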