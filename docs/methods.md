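# Methods

## Problem and model

A dental CBCT slice is a 2-D field of Hounsfield-like intensities in which
soft tissue sits low, enamel/dentin around 1500–2500 HU, and metal
restorations at 4000+ HU. The task is 3-class per-pixel labelling
(background / tooth / metal). The segmentation network is an
encoder–decoder in the DeepLabV3+ lineage whose contextual block — the
local enhancement (LE) module — replaces plain ASPP with a design biased
toward nearby context, on the premise that tooth boundaries correlate most
with close-by pixels.

**LE module.** Given an input feature X_t with C channels, six parallel
branches each emit B channels at X_t's spatial size: one 1×1 convolution;
four 3×3 depthwise-separable convolutions with dilation rates 1, 6, 12, 18;
and global average pooling followed by a 1×1 convolution, restored to the
input size as a constant field (nearest-neighbour broadcast; the source is
a 1×1 map, so any interpolation gives the same constant). The branch
outputs are concatenated to X_t4 (6B channels) and a 3×3
depthwise-separable convolution reduces the width to one-sixth, giving X_t5
(B channels). Each branch convolution and the reduction carry batch-norm +
ReLU (construction flag `use_bn=False` exposes the raw linear path for
numerical checks).

**Decoder fusion.** In the `base_le_decoder` variant each decoder stage
applies LE to the incoming feature, bilinearly upsamples X_t5 by ×2,
concatenates the encoder skip feature C_t whose resolution is exactly twice
X_t5's (X_t6), then refines with a 3×3 convolution (X_t7) and a 1×1
convolution (X_{t+1}); the reducing depthwise-separable convolution, the
3×3, and the 1×1 each carry batch-norm + ReLU. The `base` decoder stage is
a 3×3 stride-2 transposed convolution plus a 3×3 convolution; `base_le`
prepends a single LE block to that decoder at the deepest feature.

**Heads and supervision.** Every decoder stage has an auxiliary 1×1
classifier on its post-3×3-conv feature; the main 1×1 head follows the last
stage and is bilinearly upsampled to input resolution. Training minimises
`L_main + Σ_t μ_t L_t` with μ = (0.2, 0.3) ordered shallow→deep (the deeper,
higher-resolution stage gets the larger weight). Auxiliary heads are
discarded at inference.

## Loss readings

The pixel-wise loss is printed with a softmax applied to the ground truth
as well as to the prediction. Both readings are implemented:

- `literal_eq1` (module default): cross-entropy between softmax(q) and
  softmax(p). For one-hot q this has a strictly positive floor — the
  entropy of (e, 1, …, 1)/(e + K − 1), ≈ 0.9754 nats for K = 3 — attained
  when softmax(p) = softmax(q).
- `hard_onehot`: conventional −log softmax(p)[true class], which → 0 with
  confident correct logits. This is the training default in `TrainConfig`
  because it is what "softmax cross-entropy" means operationally and what
  loss-threshold smoke checks require.

Auxiliary targets are the one-hot ground truth bilinearly downsampled to
the head's resolution (partition of unity is preserved exactly; in hard
mode the per-pixel argmax is re-encoded). The IoU-loss alternative is the
standard soft-Jaccard form `1 − mean_k Σ s_k q_k / (Σ s_k + Σ q_k − Σ s_k
q_k)` with s = softmax(p); no published formula exists for it, so the
standard form is adopted and documented as such.

## Architecture choices that were genuinely open

- **Encoder.** The full-scale encoder is a ResNet-152-style bottleneck
  stack (no 151-layer standard exists; 152 preserves the intent). The
  desk-scale default is a 4-stage plain-conv encoder with widths
  16/32/64/128 — every architectural element is exercised at a size a CPU
  trains in seconds.
- **Strides.** Encoder output stride 16, two decoder stages
  (OS16→OS8→OS4), final ×4 bilinear upsample — the DeepLabV3+ convention
  this design modifies. Skip features are taken at exactly twice the
  current decoder resolution, as the fusion contract requires.
- **Branch width B.** 256 for the full model (DeepLab convention), 32 for
  the tiny profile; the design only states that channels are decreased to
  cut computation.
- **Weight sharing.** Encoder-side and decoder-side LE blocks do not share
  weights; each is instantiated independently.
- **Main-branch weight.** Fixed at 1.0; only the auxiliary weights are
  published.

## Training

SGD with momentum 0.99, weight decay 5e-4, initial learning rate 1e-3,
batch 8 — the published recipe. The published schedule is only "descending";
polynomial decay with power 0.9 (the DeepLab convention) is the default,
with step and cosine available. Training is bit-reproducible for a fixed
seed: weight init and shuffling draw from generators derived from it.
Desk-scale profile: 64–128 px phantoms, tiny encoder, 30–50 epochs. The
full-scale profile (410² slices, 152-style encoder, 500 epochs) is
constructible but meant for GPU-class budgets.

## Phantom generator

Each phantom slice emulates an axial dental arch: `n_teeth` ellipses
(semi-axes drawn from `tooth_axes_px`, small random rotation, ±2 px
position jitter, adjacency allowed, never crossing the border) placed along
a parabola, on a constant background drawn from `background_intensity`;
metal inclusions are disks inside teeth with probability `metal_prob`.
Intensities: background −200–400, tooth 1500–2500, metal 4000–6000 HU-like
— chosen so the tooth window (3010/2006) renders teeth mid-gray with metal
saturated, and the metal window (3074/4202) isolates metal, reproducing the
clinical dual-window dichotomy. The image is blurred (σ = 0.7 px) and
corrupted with additive Gaussian noise (σ = 80 HU). Labels take priority
metal > tooth > background. Per-slice seeds derive from
`SeedSequence((seed, index))`, so any slice regenerates independently and
bit-identically.

What the phantoms do **not** model: anatomy beyond intensity ordering and
arch geometry, beam-hardening/metal-artifact streaks, partial-volume
gradients at boundaries, 3-D continuity across slices. Passing desk-scale
tests therefore demonstrates that the pipeline learns and ranks variants
under controlled conditions, not clinical-grade accuracy.

## Desk-scale benchmark sizes and what they show

- **Overfit smoke:** four repeated 64² phantoms (3 teeth, semi-axes 3–5 px,
  metal probability 0.5), tiny `base_le_decoder`, plain hard cross-entropy
  (no auxiliary terms), 200 steps — reaches ≈ 0.036 nats. With deep
  supervision enabled the total plateaus near 0.10 because 8×8 hard
  auxiliary targets cannot represent the structures; that floor is a
  property of the auxiliary resolution, not an optimisation failure.
- **Variant ablation:** 100 phantoms at 64² (82/18 split, 5 teeth,
  semi-axes 3–6 px), 3 seeds, 30 epochs, identical data/schedule across
  cells, median mIoU. On this benchmark `base_le_decoder` beats both other
  variants by a wide margin (+6–9 mIoU points) at every training length
  tried, but `base_le` trails `base` by a stable 1–2 points from 15 through
  100 epochs, with or without deep supervision and at 64² or 128². The
  interpretation: at desk scale the deepest feature is 4×4–8×8 px, where
  the dilated branches (rates 6/12/18) see almost nothing but zero padding,
  so a single LE block there adds no usable context while its
  channel-bottleneck costs capacity; LE pays off only in the decoder
  stages, where it operates at higher resolution and is fused with encoder
  skips. At clinical scale (410² inputs, 26×26 deepest feature) all
  branches are informative, which is where the single-LE variant's
  published gains arise.
- **Metal at 64².** Metal inclusions are 1–3 px disks; below the OS4
  resolution of the decoder, so desk-scale models rarely predict them and
  metal IoU sits near 0. At full scale restorations span tens of pixels.

## Numerical notes

- Dilated depthwise-separable convolution is validated against a dense
  zero-inflated-kernel brute-force convolution (max |diff| < 1e-6 for rates
  1/6/12/18); every backward pass is finite-difference checked.
- Bilinear resampling uses the half-pixel-centre convention
  (`align_corners=False` in common frameworks); it is expressed as a pair
  of 1-D interpolation matrices, making the adjoint (backward) exact.
- Batch norm: per-channel batch statistics during training, running
  averages (momentum 0.1) at eval; eps 1e-5.
- Confusion-matrix IoU: a class absent from both prediction and truth
  scores 1.0 with a warning (an empty-union convention needed for small
  batches); an `nan`/exclude mode is available. Metrics accumulate over the
  whole split, not per image. The published index ranges for the IoU
  formulas are internally inconsistent as printed; the standard
  confusion-matrix form reproduces the published tables' arithmetic.
- Checkpoints store weights plus the exact network config and refuse to
  load into a mismatched architecture.

## Known limitations

- CPU-only: full-scale (410², ResNet-152-style) training is constructible
  but impractically slow without accelerators.
- The empty-class IoU convention inflates mIoU on splits where metal never
  occurs; use `empty_class="nan"` to exclude instead.
- `read_slice` handles single-frame DICOM only (no series stitching), and
  no metal-artifact reduction is attempted.
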