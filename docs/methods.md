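# Methods

## The model

The package targets binary segmentation of elongated tubular structures
in 3D grayscale volumes under severe label scarcity: a few densely
annotated volumes, many unannotated ones, and evaluation volumes whose
ground truth exists only on a small set of discontinuous axial slices.

Two networks of different dimensionality are trained in sequence.

1. A 2D U-shaped network with hierarchical windowed self-attention
   (patch embedding, shifted-window multi-head attention blocks, patch
   merging on the way down, symmetric patch expansion with skip
   connections on the way up, and a pixel head) is trained on axial
   slices cut from the labeled volumes' sliding-window patches. Slicing
   multiplies the effective number of labeled training samples by the
   patch depth, which is the premise for trusting this network's
   predictions on unseen data.
2. The trained 2D network labels every unlabeled patch: slices are
   inferred independently, the per-slice class probabilities are merged
   back into a patch-shaped grid, and the per-voxel argmax (ties to
   background) yields a frozen pseudo-label. A 3D convolutional
   encoder–decoder is then trained on labeled patches with
   `L_sup = α·L_ce + (1−α)·L_dice` (α = 0.3) and on unlabeled patches
   with the Dice-only consistency term `L_un = L_dice(pred, pseudo)`;
   the total loss is the unit-weight sum `L_sup + L_un` with no ramp-up
   schedule. The unsupervised term uses Dice only because foreground
   voxels are rare (1–15 % here), and cross-entropy against imperfect
   pseudo-labels in that regime rewards collapsing to background.

Pseudo-labels are generated once after step 1 and never refreshed;
gradients flow through the 3D network only (verified by a dedicated
test: after backprop through `L_un`, no 2D parameter holds a gradient).

## Optimization recipe

Both steps use SGD with momentum 0.9 (no weight decay by default) under
a polynomial decay `lr = lr0·(1 − epoch/max_epochs)^0.9` from
`lr0 = 0.01`, early stopping when the validation Dice has not improved
for `patience` epochs, and restoration of the best-validation
checkpoint rather than the last epoch. The schedule is driven by
epochs, not iterations. Deployment-scale defaults are a 500-epoch cap
with patience 30; the desk-scale experiment uses a 10–12-epoch cap with
patience 3–4 (see *Problem sizes* below).

Augmentation: random axis flips for both networks (applied jointly to
image and labels), plus cut-out for the 3D network — a random box
covering ~10 % of the patch volume is zeroed in the image only, never
in the labels. In step 2 each optimization step draws one labeled and
one unlabeled batch of equal size; with no unlabeled data the loop
reduces exactly to supervised training.

## Geometry

Grids are indexed (x, y, z), z axial, 0-based, half-open ranges.
Sliding-window origins form the lattice {0, s, 2s, …} per axis with a
final origin clamped to `dim − w` whenever the lattice does not end
there, so every voxel is covered without padding; volumes smaller than
the window are zero-padded up to it. Strides larger than the window
are rejected (they would leave gaps). Patch order is z-major, then y,
then x. At inference, overlapping patch probabilities are fused by
arithmetic per-voxel averaging before the argmax; argmax ties break
toward background. Deployment defaults are a 256×256×16 window with a
128×128×8 stride; desk scale uses 32×32×8 / 16×16×4.

Resampling to isotropic voxels interpolates intensities linearly and
labels by nearest neighbour (so labels stay binary). The output
dimension per axis is `round(dim·spacing/target)` with
round-half-away-from-zero, making dimension arithmetic exact in tests;
output voxel j samples input coordinate `j·target/spacing`
(index-aligned at the origin). No intensity windowing or normalization
is applied beyond this; the phantom generator produces intensities of
order 1, and real-data users can rescale upstream.

## Losses: numerical conventions

- Soft Dice is computed on the foreground class only and per batch
  item, then averaged; this differs from batch-pooled Dice whenever
  foreground sizes vary across the batch, and is the documented choice.
- `dice_smooth = 1e-5`; an empty target with an empty prediction gives
  loss 0 (the smoothing terms cancel).
- Probabilities are floored at 1e-12 before the cross-entropy log.
- Losses consume probabilities, never logits, and never an argmax; the
  discretization to labels happens only at pseudo-label generation and
  final inference.
- A caveat the test suite documents: on an exactly empty target the
  soft-Dice gradient w.r.t. the prediction scales with the smoothing
  constant and effectively vanishes, so fits to all-background examples
  are driven by the CE term alone.

## Evaluation protocol

Dice, precision and recall are counted on foreground voxels. When both
ground truth and prediction are empty, all three metrics are defined as
1 (sparse labeled slices can legitimately contain no foreground); an
empty denominator facing a non-empty counterpart gives 0. For sparsely
labeled volumes every metric uses only voxels on labeled slices, in a
fixed deterministic order; predictions elsewhere cannot influence any
number (bit-invariance is tested). Experiments are repeated over three
training seeds; per-case metrics are averaged across seeds first, then
mean and SD (population SD) are taken across cases. Arms are compared
with a two-sided paired Wilcoxon signed-rank test: zero differences
dropped, exact null distribution for n ≤ 12 untied differences, normal
approximation with tie correction otherwise, p = 1 by convention when
every difference is zero.

## The phantom generator

Each phantom is a union of `n_tubes` smooth random tubes: a random walk
with persistent direction gives control points, a cubic spline smooths
them, the densely sampled centerline is dilated by a Euclidean ball of
radius drawn from `tube_radius_range` (2–4 voxels by default).
Ellipsoidal confounder blobs receive an intensity within ±10 % of the
tube intensity but a background label; the first is anchored against a
tube's surface so foreground always touches a same-intensity distractor.
Gaussian noise is added last, so changing only `noise_sd` changes
intensities but never labels. The generator redraws (boundedly) until
the foreground fraction falls in 1–15 % of voxels, keeping class
imbalance in the range seen clinically. Sparse evaluation masks keep a
uniformly sampled 10 % of axial slices — at 32-slice desk scale this
yields ~3 labeled slices per volume, matching the handful of annotated
slices per sparse clinical volume; the label grid itself is unchanged.
Cohort generation draws those slices from the planes that intersect the
structure (annotators label slices where the organ is visible; a
uniformly random plane of a 64×64×32 phantom is often organ-free, which
no clinical sparse annotation is). The lower-level `sparsify_labels`
keeps plain uniform sampling as its default, and foreground-free
labeled slices remain fully supported by the data model and metrics.
Everything is a pure function of (spec, seed), with per-case seeds
spawned from a master seed so a case is stable regardless of cohort
composition.

What the phantoms do **not** emulate: CT physics (beam hardening,
partial volume, air–fluid levels), peristaltic deformation, contact
between distinct organs with different textures, or anisotropic
acquisition artifacts. Passing tests therefore demonstrate the
correctness and the qualitative behaviour of the pipeline (pseudo-label
consistency helps when labels are scarce), not clinical-grade accuracy.

## The autodiff engine and networks

The networks run on a small reverse-mode automatic-differentiation
engine over NumPy arrays written for this package: broadcasting
arithmetic, matmul, elementwise nonlinearities, shape ops, an index
gather (whose backward is a scatter-add) and axis reductions.
Convolutions are im2col gathers followed by a shared-weight matmul, so
their gradients come from the engine's primitives; gradient correctness
is pinned by finite-difference tests down to 1e-7. Float32 is used for
network training, float64 wherever loss arithmetic is checked.

Architecture notes: the 2D network follows the shifted-window attention
design (window 4 at tiny scale, two stages of depth 2, patch size 4)
without relative position biases — at these window sizes the expansion
head provides sufficient positional specificity, and the omission keeps
the engine small. The 3D network uses strided-convolution downsampling
and nearest-neighbour upsampling with instance normalization. One
initialization detail matters: biases are initialized uniformly in
±1/√fan_in rather than at zero, because a zero-initialized patch
embedding maps constant background patches to the exact zero vector,
where LayerNorm's gradient is amplified by 1/√eps and the first SGD
step destroys the embedding.

## Problem sizes

The shipped experiment (`mdcl.experiment`, also run by
`scripts/acceptance.py`) uses 64×64×32 phantom volumes — 2 labeled + 6
unlabeled for training, 2 validation, 4 test — the 32×32×8 window with
16×16×4 training stride, tiny network presets (embed 24 / base 8), 6
optimization steps per epoch, a 16-epoch cap for step 2 and 12 for
step 1 with patience 6 (validation every other epoch in step 2, so
patience spans three validation rounds), and three training seeds per
arm. Validation and
test inference stitch non-overlapping tiles (stride = window): on
noise-free phantoms the overlap averaging changes Dice negligibly, and
half-window users can set `TrainConfig.eval_stride`. These sizes were
chosen so a full paired comparison trains on a single CPU core in
minutes while still showing the pipeline's qualitative behaviour; they
are the package's desk-scale defaults, not tuned quantities.

## Known limitations

- No confidence thresholding of pseudo-labels; every pseudo-labeled
  voxel enters `L_un` with equal weight.
- No iterative pseudo-label refresh; the two steps run exactly once.
- The 2D network trains from random initialization; with pretrained
  encoders step 1 would likely need fewer epochs.
- Inference fusion is plain averaging (no Gaussian window weighting or
  test-time augmentation).
- The engine is CPU-only and single-threaded beyond BLAS; deployment
  scale (256×256×16 windows) is out of reach without a GPU framework,
  which the module boundaries deliberately permit swapping in.
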