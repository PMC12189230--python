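# Methods

This note records what the package implements, the assumptions baked into it,
why the defaults are what they are, and what the synthetic data generator does
and does not emulate.

## Problem setting

Multimodal ophthalmic diagnosis pairs a 2-D projection image (for example a
fundus photograph or an OCTA en-face projection) with a 3-D volume acquired
as an ordered stack of cross-sectional slices (OCT/OCTA B-scans). Clinical
datasets of this kind are small (hundreds of eyes) and class-imbalanced
(roughly two healthy eyes per diseased eye is typical). The package trains a
dual-branch convolutional classifier on such pairs and evaluates it with
support-weighted metrics appropriate for imbalance.

## Model

### Backbone branches

Each modality has its own residual branch with separate weights. A branch is:

- **Stem**: depthwise 3×3 convolution (stride 2) → pointwise 1×1 convolution
  → batch norm → ReLU → 3×3 max pool (stride 2). Total stride 4, so a
  224×224 input leaves the stem at 56×56. The depthwise-separable split keeps
  the parameter count of the first layer small, which matters on small
  datasets.
- **Four residual stages** in a 3-4-6-3 block layout with channel widths
  (64, 128, 256, 512) and strides (1, 2, 2, 2), giving the spatial ladder
  56 → 28 → 14 → 7. Each block computes
  `ReLU(shortcut(x) + BN(conv(FTCA(ReLU(BN(conv(x)))))))`, where the shortcut
  is the identity when shapes match and a strided 1×1 projection otherwise.

Batch normalisation follows every convolution. That is an assumption, not an
option: at these depths the plain-SGD-style signal propagation without
normalisation is untrainable in practice, and all defaults were validated
with BN in place. BN uses batch statistics in training mode and running
averages (momentum 0.1) in eval mode, which makes eval-mode predictions
independent of batch composition (tested).

The 3-D volume is consumed as a stack of 2-D slices pushed through the *same*
branch (shared weights), and the per-slice feature maps are averaged across
the stack. Mean aggregation was chosen over max because it makes the result
invariant to slice order and gives every slice a gradient; max aggregation is
available via `ModelConfig(slice_aggregation="max")` for volumes where a
single pathological slice should dominate.

### FTCA: the hybrid attention block

Inside every residual block sits the frequency/channel/spatial attention
module:

1. **Frequency attention.** The input channels are split into a local half
   (⌈C/2⌉ channels) and a global half. The local path is a 3×3 convolution;
   the global path applies a 2-D FFT, stacks real and imaginary parts as
   channels, mixes them with a 1×1 convolution, and inverse-transforms back,
   giving that path a receptive field covering the whole plane in one step.
   Two 1×1 cross-talk convolutions exchange information between the paths.
   The spectral 1×1 mixing is linear by default
   (`spectral_activation="identity"`); a ReLU variant is available but breaks
   the exactness of the spectral oracle test and is off by default.
2. **Channel attention.** Global average- and max-pooled channel descriptors
   pass through a shared two-layer bottleneck MLP (reduction 16, clamped so
   the bottleneck never drops below one unit); the two outputs are summed and
   squashed by a sigmoid into a per-channel gate.
3. **Spatial attention.** Channel-wise mean and max maps are concatenated and
   convolved with a single 7×7 kernel; a sigmoid gives a per-pixel gate.

Channel and spatial gating are composed **sequentially** (channel first, then
spatial on the channel-gated tensor). A parallel variant that multiplies both
masks onto the frequency output at once is available via
`ModelConfig(ftca_mode="parallel")`; sequential is the default because the
spatial gate then sees channel-reweighted statistics, which in the desk-scale
ablations trained at least as well and matches the usual tandem-attention
composition.

### DFF: dual-feature fusion

The two branch outputs (bilinearly aligned if their grids differ) are fused
by:

1. **Multi-scale grouped convolutions** per stream: a 3×3 and a 5×5 grouped
   convolution (4 groups, clamped to a divisor of the width) summed and
   rectified. Two scales keep the cost linear in width while still mixing
   neighbourhood context; group counts fall back gracefully for thin test
   models.
2. **Fusion attention gate (FAG)**: both streams are projected to a common
   width by 1×1 convolutions `W_i`, `W_v`, and a gate
   `sigmoid(Conv1x1(ReLU(W_i·F_img + W_v·F_vol)))` combines them. The default
   is the **convex** combination `g·P_img + (1−g)·P_vol`, which makes the
   gate directly interpretable as a per-pixel modality preference and keeps
   the fused magnitude bounded by the stream magnitudes. An additive variant
   `g·(P_img + P_vol)` is available (`fusion_gate_mode="sum"`).
3. **Tandem channel and spatial attention** on the fused map, then a global
   average pool and a linear head (softmax lives in the loss).

For ablations, DFF can be replaced by a plain concatenation + 1×1 convolution
(`use_dff=False`), and FTCA can be removed from the residual blocks
(`use_ftca=False`).

## Loss and metrics

Training minimises the mean multiclass focal loss
`−(1−p_t)^γ · log p_t` with γ = 3 by default; γ = 0 recovers plain
cross-entropy exactly (special-cased so no `0^0` ambiguity arises).
Probabilities are clamped at 1e-12 before the log, so a confidently wrong
model produces a large finite loss rather than an overflow. Optional
per-class weights multiply the per-sample terms.

Evaluation reports accuracy plus support-weighted precision, recall and F1
from the confusion matrix. A class that is never predicted contributes
precision 0 (and still carries its support weight) instead of raising a
division error; support-weighted recall therefore equals accuracy, which the
tests assert as a consistency check.

## Training recipe

Adam (β₁ = 0.9, β₂ = 0.999) at learning rate 1e-4, batch size 4, up to 100
epochs, with best-validation-accuracy checkpointing. One master seed fans out
through `numpy.random.SeedSequence` into three independent streams (weight
initialisation, data ordering, augmentation), so a run is bit-reproducible on
CPU — the acceptance suite checks run logs for bitwise equality. A leakage
guard refuses overlapping sample ids between partitions before any training
starts. Optional early stopping on training accuracy exists for the
desk-scale overfit checks.

Transfer loading (`load_pretrained`) migrates backbone weights by name and
shape; by default the attention blocks, fusion module and head are left
freshly initialised — the intended contract when moving feature extractors
between related tasks.

## Synthetic data generator

The generator emulates the *statistical shape* of a paired ophthalmic
dataset, not its appearance:

- **Image** (fundus-like): a soft-edged bright disc with a darker central cup,
  oriented sinusoidal vessel-like texture, and Gaussian pixel noise. Class
  `k` (0 = healthy-like) increases the cup-to-disc ratio
  (0.30 + 0.15·e·k/(K−1)), the texture frequency (4 + 2·e·k) and the global
  intensity (+0.04·e·k), where `e` is `effect_size`.
- **Volume** (OCT-like): horizontally undulating layered bands over a noisy
  background; class `k` thickens the middle band (0.12 + 0.06·e·k/(K−1)).
- **Class mix**: probabilities (0.5, 0.25, 0.25) over three classes, matching
  the roughly 2:1 healthy-to-diseased imbalance of small clinical cohorts.
- `effect_size=0` removes every class cue, so any probe must fall to chance —
  a negative control asserted in the tests.

It does **not** emulate scanner physics, speckle statistics, real vessel
topology, inter-eye correlation, or segmentation-grade anatomy. Conclusions
about *relative* architecture performance at desk scale are the intended use;
absolute accuracies on this data say nothing about clinical performance.

Augmentation applies a shared random crop (scale 0.9), a horizontal flip
(p = 0.5) and a rotation (±15°, chosen so the phantom stays in frame)
consistently to both modalities, then with probability 0.6 adds Gaussian
noise with variance drawn uniformly from [0.01, 0.05], clipping back to
[0, 1].

Splitting is stratified 80/20 (test), then 80/20 again (validation), with
largest-remainder rounding so the global sizes are exact: n = 100 always
yields 64/16/20, disjoint and exhaustive.

## Numerical choices

- The package carries its own reverse-mode automatic differentiation engine
  on NumPy arrays (float64 throughout). Every primitive's gradient is
  finite-difference checked in the test suite; the FFT pair's adjoints
  (`fft2_stack`/`ifft2_real`) are derived analytically and verified the same
  way.
- Convolution is im2col + grouped matrix multiplication; the backward pass
  folds gradients with a small loop over kernel offsets. float64 keeps the
  oracle comparisons tight (1e-5 tolerances with slack to spare).
- Softmax is max-shifted; the shift enters the graph as a constant, which is
  exact because softmax is shift-invariant.
- Max pooling splits gradients evenly among tied maxima (a valid
  subgradient), and the max reduction used in attention pooling does the
  same, so gradients never silently vanish on plateaus.

## Desk-scale acceptance runs

The published-scale experiments behind this architecture need clinical
datasets and GPU budgets. The package's own acceptance checks are therefore
property-based and scaled down, with sizes chosen to fit a single CPU core:

- **Overfit check**: reduced widths (8, 16, 32, 64), 64×64 inputs, 4 slices,
  48 training samples, ≥ 95% training accuracy within 50 epochs
  (typically reached around epoch 35–40 in a few minutes).
- **Ablation harness**: 72 samples, three split seeds, 20 epochs at learning
  rate 3e-4 (the larger step compensates for the short schedule). The
  report averages each variant's metrics over the seeds; every variant's
  averaged accuracy must beat the 0.5 majority-class baseline, and the
  full model is expected (softly — reported, not hard-failed) to be within
  0.05 of the best single-module variant.

These sizes are this package's own documented choices for a CPU-only desk
check; they are deliberately small and their absolute numbers should not be
compared against any published results.

## Limitations

- CPU-only and written for clarity over speed; wall-clock cost grows quickly
  with width and resolution.
- The synthetic generator's cues are low-order (intensity, thickness,
  frequency); it cannot detect failure modes that only textures or topology
  would expose.
- Desk-scale test sets are tiny (≈ 14 samples per seed in the ablation), so
  individual accuracies are quantised in steps of ~0.07 and only
  seed-averaged comparisons are meaningful.
- Batch-norm statistics are assumed reliable at batch size 4; for batch size
  1 training the defaults would need group or layer normalisation, which is
  not implemented.
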