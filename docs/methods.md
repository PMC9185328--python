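# Methods

## Model and procedure

`troposearch` treats hyperparameter selection for a transfer-learning image
classifier as black-box minimization over the unit hypercube. A candidate
configuration is a vector `x ∈ [0, 1]^D` with `D = 16`; decoding and search
are deliberately decoupled, so the optimizer never sees the discrete
structure of the space.

### Solution decoding

List-like domains (losses, optimizers, scaling techniques, booleans, the
discrete batch/rotation/learn-ratio grids) of length `L` are decoded with
the 1-based index `clamp(⌈x·L⌉, 1, L)`. This convention reproduces the
canonical worked example (0.75 against 12 batch sizes → index 9 → batch 36)
and is total on the closed interval: `x = 0` clamps to the first entry and
`x = 1` lands on the last. Continuous ranges interpolate linearly.
Boolean domains are ordered (Yes, No), so an element of 0 decodes to True.

Fifteen hyperparameters occupy sixteen slots because the brightness
augmentation range is an ordered pair: its two elements are each mapped to
`[0.5, 2.0]` and returned sorted. Augmentation sub-parameters are always
decoded; when the augmentation flag decodes to "No" they are retained but
marked inactive, so a configuration is always fully populated.

### The troop updates

The optimizer follows the standard artificial-gorilla-troops scheme. Per
step the coefficients are `F = cos(2r₄) + 1`, `C = F(1 − t/T_max)`,
`l ~ U(−1, 1)`, `L = C·l`. Exploration chooses, per member: uniform
re-sampling within bounds (probability `p`), a move toward a random member
`(r₂ − C)·X_r + L·(Z ∘ X_i)` with `Z ~ U(−C, C)^D`, or a move relative to a
known place `X_i − L(L(X_i − X_r) + r₃(X_i − X_r))`. Exploitation follows
the silverback (`GX = L·M·(X_i − X_sb) + X_i`, `M` the elementwise
`g`-power mean of the troop with `g = 2^L`) while `C ≥ w`, else performs
the competition move `GX = X_sb − (X_sb·Q − X_i·Q)·A` with `Q = 2r₅ − 1`
and `A = β·E`, `E` a per-dimension standard normal vector when a fresh
uniform draw is ≥ 0.5 and a broadcast scalar normal otherwise.

Defaults `p = 0.03`, `β = 3`, `w = 0.8` follow common GTO practice. Both
phases are followed by a greedy replacement (`X_i ← GX_i` iff the candidate
is strictly cheaper), so the best-fitness trace is non-increasing by
construction. Candidates are clipped to the box after every move. Members
whose candidate fitness is non-finite are skipped and flagged rather than
replaced.

Randomness is consumed in a documented fixed order (per step: `r₄`, then
`l`, then a member-major loop drawing the branch selector before the
branch's own draws, partner index before per-dimension vectors). This makes
seeded runs bit-reproducible and lets the test suite compare a full small
trajectory against an independent straight-line transcription of the update
rules driven by the same stream.

### Fitness

Fitness is `1 − accuracy` on the evaluation set. The loss function itself
is a searched hyperparameter, so raw loss values are not comparable between
solutions; accuracy is, and under single-label micro aggregation it equals
micro recall `TP/(TP+FN)`. By default the trained model is evaluated on the
entire dataset; `eval_on="test"` restricts evaluation to the held-out split
and is the leakage-free option. Training divergence returns an infinite
fitness sentinel, which the greedy replacement treats as "never accept".

### The toy network

The built-in trainable model is implemented directly on numpy: mean-pool to
32×32, one 3×3 convolution (8 filters, ReLU), global average pooling, batch
standardization of the 8 pooled features (no learned affine; running
statistics, seeded from the first batch, are used at inference), a 16-unit
ReLU dense layer, inverted dropout at the searched rate, and a K-way
softmax head. The across-image variation of GAP responses is orders of
magnitude smaller than their per-filter baselines, which is why the feature
standardization stage exists; without it the classifier head sees an
ill-conditioned problem and converges to the class prior within any
realistic epoch budget.

All six searched losses are implemented with exact gradients through the
softmax (verified against finite differences), and all eleven optimizers
are implemented as standard update rules. Default step sizes are chosen for
a small network on desk-scale data: 0.01 for the adaptive methods, 0.05 for
the SGD family, and 1.0 for AdaDelta (whose effective step is internally
normalized). The hinge-family losses operate on softmax outputs with ±1
target encoding, matching how they are conventionally reported for
probability outputs.

The "TL learn ratio" (1–100) is the percentage of backbone layers left
trainable, counted from the output end and rounded, with at least one
backbone layer always trainable; the softmax head always trains. The toy
network's backbone has two layers (conv, dense), so ratios below 75% train
the dense layer only and higher ratios unfreeze the convolution too.
Heavier ImageNet-pretrained backbones are out of the package core; a
builder registry (`troposearch.fitness.register_backbone`) lets a
deep-learning backend provide them without touching the search machinery.

## Preprocessing

* **SNR cleaning** — the signal-to-noise ratio of an image is defined as
  mean over standard deviation of its pixel intensities, one number per
  image; images below the threshold (default 1.15) are dropped before
  resizing. A constant image has infinite SNR and is always kept.
* **Scaling** — four whole-image techniques: `X/max(X)`,
  `(X−μ)/σ`, `(X−min)/(max−min)`, `X/|max(X)|`. Degenerate inputs (zero
  denominator) raise rather than silently returning zeros; the fitness
  harness passes constant images through unscaled.
* **Resizing** — bicubic spline interpolation to `128×128×3` (grayscale
  replicated across channels); constant images are preserved exactly.
* **Splitting** — stratified: 15% test by default, then 10% of the
  remaining training share carved out for validation (the validation share
  is a package choice; only the 85/15 outer split is prescribed).
* **Balancing** — minority classes are oversampled with augmented copies
  until per-class counts match the majority in every training epoch; no
  undersampling. The augmenter samples rotation uniformly in ±range,
  fractional shifts, shear, zoom in `[1−z, 1+z]`, Bernoulli(0.5) flips
  where enabled, and a multiplicative brightness factor uniform over the
  configured pair. An identity-configured augmenter is pixel-exact.

## Metrics

Multi-class results are micro-aggregated: one-vs-rest TP/TN/FP/FN summed
over classes, then standard textbook formulas. Micro aggregation was chosen
because it reproduces the published reference tables: recall, specificity,
Youden index, FNR and fallout recompute to printed precision for all
sixteen published model columns, and precision/FDR/MCC for most. The cells
that do not match (they came from streaming/thresholded metric variants in
the source experiments) are enumerated explicitly and reported as
discrepancies rather than asserted; the AUC here is one-vs-rest
macro-averaged trapezoidal ROC integration and is likewise not expected to
match streaming AUC variants bit-for-bit. Undefined metrics (zero
denominator) are reported as NaN, never as 0. FBeta defaults to β = 2 and
is exposed as a parameter.

## Synthetic data

The generator renders grayscale "axial slices": a bright elliptical
cortical ring (intensity ≈ 0.72 on a 0.35 background) around a dark
ventricle, with additive Gaussian noise (σ = 0.05) and small per-image
geometric jitter. The class signal is geometric — the ventricle radius
grows and the ring dims monotonically with class index, emulating atrophy
grades — so the task is learnable by a small CPU-trained network and a
linear read-out of mean intensity separates the extreme classes. A
configurable fraction of images is replaced by speckle noise (sparse bright
pixels on near-black) whose moments put the SNR near 0.6, safely below the
1.15 cleaning threshold, with ground truth recorded in a manifest. Images
are quantized to the 8-bit grid in memory so PNG round-trips are lossless.

What the generator does **not** emulate: MRI physics (bias fields, partial
volume, acquisition artifacts), anatomical variability, texture-based class
signal, or class imbalance between pathological stages. Passing tests
demonstrate that the pipeline's machinery is correct and that the search
improves a learnable objective — not that any particular accuracy level
transfers to real MRI data.

## Problem sizes and numerical choices

The test suite runs everything at desk scale as a design choice: synthetic
datasets of 36–160 images at 32–64 px, troop sizes 3–6 with 1–2 iterations
for end-to-end runs, and the optimizer benchmark at N=30, D=16, 500
iterations over 20 seeds on the sphere function (bounds ±100), where the
median final cost reaches numerical zero. Checkpoints store the full troop
state plus the generator state, so an interrupted run resumes
bit-identically; resuming is only well-defined for the same `T_max`, since
the decay coefficient depends on it. Ties in greedy replacement keep the
incumbent (strict inequality); the silverback is the argmin, first index on
ties.

## Known limitations

* The pretrained backbones are registry plugins, not built in; the package
  core is validated with the toy network only.
* Whole-dataset evaluation (the default, kept for fidelity to the original
  experimental protocol) mixes training images into the fitness estimate;
  use `eval_on="test"` for honest generalization numbers.
* The augmentation search block is unconditional in dimensionality: the
  sub-parameters are always part of the vector even when the flag decodes
  to off, which adds benign redundancy to the search space.
* FTRL's proximal reformulation effectively re-derives weights from its
  accumulator state, so it behaves poorly from a warm nonzero
  initialization — as an optimizer *option under search* this is simply a
  configuration the troop learns to avoid.
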