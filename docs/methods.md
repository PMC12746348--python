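# Methods

This note records the scientific and numerical decisions behind `scdunet`:
what each component computes, which parameters matter, what the synthetic
phantoms do and do not emulate, and where the design was genuinely open.

## Network

**Encoder.** Each of the four encoder stages runs two cascaded residual
blocks, `x' = x + F1(x) + F2(x + F1(x))`, where every residual branch is
[3×3 conv → batch norm → ReLU] twice. Identity shortcuts are exact: with
zeroed convolutions and identity normalisation a stage is a no-op, which the
tests assert bitwise. Downsampling is a stride-2 3×3 convolution rather than
max-pooling; this keeps the downsampling step learnable and makes the
encoder path count 5 convolutions per stage (4 residual + 1 downsampling),
i.e. 20 for the default depth. A stem convolution lifts the single input
channel to the base width before stage 1; it is not part of that count.
Channels double per stage from `base_channels` (64 at full scale, 1024 at
the bottleneck; the test preset uses 8 → 128).

**SC attention.** The module is the element-wise *sum* of a channel
squeeze-excitation gate and a coordinate-attention gate. Channel branch:
global average per channel, then FC(C → max(C/r, 4)) → ReLU → FC(→ C) →
sigmoid; the floor of 4 keeps the bottleneck meaningful for narrow test
networks. Coordinate branch: height- and width-pooled profiles are
*concatenated* along the spatial axis into an (H+W)-long sequence of
C-vectors, reduced by one shared 1×1 convolution with ReLU, split back into
the two directions, and expanded per direction to C channels with a sigmoid.
Concatenation (not addition) of the pooled profiles is forced by the
declared intermediate shape of the fused sequence, (H+W)×1×C. The default
placement is after each encoder residual stage, with the skip connection
tapped *after* attention so the decoder receives recalibrated features; a
config enum moves the module to the decoder or both paths.

**Dense ASPP.** Three 3×3 branches with dilations 1/2/3 and "same" padding.
Branch *l* consumes the concatenation of the bottleneck input with the
outputs of branches with strictly smaller dilation (`S_l = {i : d_i < d_l}`);
the final 1×1 projection restores the bottleneck width. Non-increasing
dilation lists are rejected: under sequential evaluation a repeated rate
would make a branch's input set ill-defined. The per-branch growth width
defaults to a quarter of the bottleneck width — the architecture leaves this
free, and a quarter keeps the concatenation projection affordable. The
receptive-field algebra is `RF = k + (k−1)(d−1)` per branch and
`K = K1 + K2 − 1` for stacked fields. Note the pyramid maximum of 13 is a
*chain* property: the two largest branch fields alone give 7 + 5 − 1 = 11;
13 arises because the d=3 branch (field 7) sits on the d1→d2 chain whose
accumulated field is also 7. `max_receptive_field` implements this recursion,
and the acceptance script verifies it against the measured impulse-response
footprint of a live forward/backward pass.

**Decoder and geometry.** Four stages of 2× upsampling (transposed
convolution by default; a bilinear-then-conv alternative is selectable),
skip concatenation, and two conv-norm-ReLU layers. Inputs must be divisible
by 2^stages. With 448×448 inputs four halvings give a 28×28 bottleneck
(448/2⁴ = 28); a 32×32 bottleneck would correspond to 512×512 inputs. The
implementation follows the arithmetic.

**Weight initialisation** is Kaiming-uniform from a single generator seeded
by `NetworkConfig.init_seed`, so identical configs build bit-identical
networks.

## Autodiff backend

The network runs on a small reverse-mode autodiff engine over NumPy arrays
(`scdunet.nn`): broadcasted arithmetic, matmul, reductions, shape ops, ReLU/
sigmoid/exp/log, and two fused primitives — im2col/GEMM 2D convolution with
stride and dilation (backward via a k² slice-accumulation col2im) and
kernel-2/stride-2 transposed convolution. Batch norm is composed from
primitive reductions, so its gradients come for free; running statistics use
momentum 0.1 with an unbiased variance update. Gradients of every primitive
and of composed blocks are tested against central finite differences; block
forwards are tested against naive loop-based references. The engine keeps
whatever float dtype it is given: training uses float32 (BLAS sgemm),
oracle-equivalence tests run the same graph in float64.

## Loss

`L = α·L_focal + (1−α)·L_dice`, α ∈ [0,1], default 0.7. The focal term
computes per-pixel softmax cross-entropy with natural logarithms, sets
`p_t = exp(−CE)` *per pixel* (per-sample focusing, not a batch-mean
shortcut), modulates by `(1−p_t)^γ` with γ = 2, and averages. The Dice term
is one minus the mean soft Dice over classes, where per-class Dice pools
intersection and size sums over the whole batch with ε = 1e−8 smoothing. By
default only the foreground classes (GTVp, GTVn) enter the mean: including
the overwhelmingly dominant background would dilute exactly the imbalance
correction the compound loss exists for; `dice_classes="all_classes"`
restores it. Cross-entropy carries no class weights. The combination is
exactly affine in α, and γ = 0 reduces the focal term to plain
cross-entropy — both are asserted, not assumed.

`alpha_grid_search` evaluates a caller-supplied training routine over an α
grid (default 0 … 1 in steps of 0.1) across folds and tabulates mean DSC and
HD95 per α. On phantoms this exercises the protocol; it does not claim to
reproduce clinical-data ablation values.

## Preprocessing and folds

*Valid region* for intensity normalisation is interpreted as strictly
positive voxels — MRI air background is ≈ 0 and carries no anatomy. The
volume is z-scored over that region; invalid voxels map to the minimum
normalised value so they remain darkest; a constant valid region normalises
to zeros with a warning. Slices are resized to the network side (448 at full
scale) with bilinear interpolation for images and nearest-neighbour for
masks, so labels are preserved exactly; scaling (not cropping) was chosen
for the 512 → 448 step. Slice screening — keeping only slices with at least
one tumor voxel — applies to *training* data only; validation and test
volumes are always evaluated in full, since screening at test time would
leak labels.

The partition protocol shuffles ids under a seed, reserves a third (rounded
down) as the independent test set, and splits the remainder into five
disjoint validation blocks; each fold trains on the other four. With 150
cases this yields the 50 / (80 train + 20 val) split. The actual fold
membership of the original study is unknown; the seed-controlled shuffle is
the contract.

## Training protocol

Adam (β = 0.9/0.999) at an initial learning rate of 1e-4, batch 16, up to
1000 epochs at full scale, with a cosine-annealed learning rate bounded
below by 1e-5; the decay period defaults to 10 000 optimisation steps, after
which the rate stays at the floor. Early stopping monitors the validation
*mean foreground aggregated DSC* — the mean over GTVp/GTVn of the DSC
computed from voxel counts pooled over the validation volumes — and stops
exactly `patience` (default 20) epochs after the last improvement, keeping
the best checkpoint. The monitored quantity is a design choice; the protocol
fixes only the mechanism and patience. Batches sample screened lesion slices
uniformly without class oversampling, and no data augmentation is applied.

Full-volume inference normalises the volume, resizes every axial slice to
the network side, takes the argmax over class logits, and restores the
native in-plane shape with nearest-neighbour interpolation before metrics
are computed — HD95 is therefore volumetric and in millimetres.

## Metrics

DSC is `2|A∩B|/(|A|+|B|)`; when a structure is absent from both masks the
value is undefined and reported as `None` (excluded from means, counted in
the report) — substituting 0 or 1 would distort averages. The aggregated DSC
pools intersection and size counts across cases before the ratio, which
equals the (|gt|+|pred|)-weighted mean of per-case DSCs and is the robust
summary under empty ground-truth structures; this identity is tested
numerically. The Hausdorff distance is the symmetric max-min over point sets
in physical coordinates. HD95 takes the 95th percentile of the *pooled
bidirectional* boundary-to-boundary distances — the convention of
segmentation challenges — with boundaries defined by face adjacency (array
edges count as background). Both are validated against exhaustive
brute-force oracles.

## Phantom generator

Each case is a 3D volume with an ellipsoidal "head" of absolute-Gaussian
soft-tissue intensities (mean 35, sd 15) in exact-zero air, plus lesions:
anisotropic ellipsoids perturbed by smoothed noise and thresholded, giving
smooth connected blobs whose z-extent respects the anisotropic voxel
spacing (0.5×0.5×2.0 mm by default). The target foreground fraction is
drawn log-uniformly from the spec range — producing the right-skewed
fraction distribution of the emulated cohort — and enforced by iterative
radius correction; an infeasible range raises rather than silently clipping.
At most one GTVp is placed near the in-plane midline (the oropharyngeal
position) and GTVn lesions laterally (neck levels), with later lesions
carved around earlier ones so the two labels never overlap. Tumor voxel
intensities are absolute-Gaussian with per-lesion mean from 50–100 and sd
from 0–50; the two classes are deliberately *identical* in intensity
distribution, so a segmenter can separate them only through the positional
prior — which is what the coordinate-attention pathway is built to exploit.

What the phantoms do **not** emulate: anatomy (airway, bone, muscle
texture), bias fields, Rician noise proper (absolute-Gaussian is an
approximation), fat suppression variability, multi-sequence appearance, or
inter-observer label noise. Passing tests on phantoms therefore demonstrate
that the pipeline is implemented correctly and can learn position- and
intensity-defined targets under heavy class imbalance — not that it reaches
clinical-grade accuracy on real MRI.

## Problem sizes and presets

The default `PhantomSpec` keeps the cohort's voxel-fraction band
(0.000–0.004, log-uniform with a small-lesion floor) on a 64×64×32 grid; the
generator accepts full-size shapes. The training preset
(`phantom.training_preset`) enlarges the relative lesion size to a
0.004–0.015 fraction band with one GTVn: after the 8× in-plane coarsening
from the clinical grid, cohort-band lesions would span only a few voxels and
their one-voxel boundary shell would dominate the Dice denominator, which
measures discretisation rather than learning. The network test preset
(`training.toy_preset`) is 64×64 inputs, 8 base channels, reduction ratio
4, batch 4, learning rate 2e-3 cosine-annealed over 1200 steps, at most 30
epochs — the learning rate is scaled up in proportion to the tiny network
and short schedule. On a 12-case cohort (9 train / 3 val) this configuration
reaches a validation mean foreground DSC around 0.9 within 30 epochs on a
single CPU; the learning-sanity test asserts ≥ 0.8.

## Known limitations

- 2D slice-wise segmentation only; no inter-slice context (a 3D extension is
  out of scope).
- The NumPy backend is single-device and unbatched across workers; full-scale
  (448², base 64) training is supported by the code but is orders of
  magnitude slower than a GPU framework — the package's purpose is
  correctness and protocol fidelity at test scale.
- Checkpoints store raw weights plus config; no cross-version migration.
- `alpha_grid_search` at full scale is 11 × 5 training runs; use the toy
  presets for exploration.
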