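# scdunet

2D segmentation of head-and-neck gross tumor volumes on T2-weighted MRI.
`scdunet` implements SCDU-Net — a U-shaped encoder–decoder that combines a
cascaded-residual encoder, a spatial–channel dual attention (SC) module and a
selectively connected dense atrous spatial pyramid pooling (Dense ASPP)
bottleneck — together with its combined focal/Dice training loss, the
preprocessing and five-fold cross-validation protocol, and an evaluation
suite built around the aggregated Dice coefficient and the 95th-percentile
Hausdorff distance. A synthetic phantom generator emulates the statistical
structure of a head-and-neck MRI cohort, so the entire pipeline is testable
without any clinical data download.

The intended audience is researchers in medical image analysis and
radiotherapy planning who want a self-contained, dependency-light reference
implementation of these components. The network and its training loop run on
a small NumPy reverse-mode autodiff engine included in the package
(`scdunet.nn`), so the only heavy requirement is NumPy/SciPy.

## The model

- **Encoder** — four stages. Each stage applies two cascaded residual blocks,
  `x' = x + F1(x) + F2(x + F1(x))`, where each `F` is
  [3×3 conv → batch norm → ReLU] ×2, then recalibrates features with the SC
  module and halves the resolution with a stride-2 convolution (channels
  double, 64 → 1024 at full scale). Counting 4 residual convolutions plus the
  downsampling convolution per stage gives a 20-convolution encoder path.
- **SC attention** — the element-wise sum of two gates: channel
  squeeze-excitation, `S = σ(FC2(δ(FC1(z))))` with `z` the per-channel global
  average, and coordinate attention, which pools separately along height and
  width, mixes the pooled profiles through a shared 1×1 convolution, and
  emits direction-aware gates `α_h ∈ (0,1)^H`, `α_w ∈ (0,1)^W` applied as an
  outer product.
- **Dense ASPP bottleneck** — three 3×3 branches with dilation rates 1/2/3.
  Branch *l* consumes `[x0, {x_i : d_i < d_l}]`: the original feature map
  plus the outputs of strictly-smaller-dilation branches. A dilated kernel
  sees `RF = k + (k−1)(d−1)` pixels (3/5/7 here); stacked fields superpose as
  `K1 + K2 − 1`, and the deepest dense chain reaches a 13-pixel maximum
  receptive field.
- **Loss** — `L = α·L_focal + (1−α)·L_dice` with `α = 0.7` by default:
  per-pixel focal cross-entropy `(1−p_t)^γ · CE` (γ = 2, `p_t = exp(−CE)`)
  plus one minus the mean soft Dice over the foreground classes
  (ε = 1e−8 smoothing).
- **Metrics** — per-structure DSC (GTVp = label 1, GTVn = label 2), the
  aggregated DSC that pools voxel counts across cases before the ratio, and
  volumetric HD95 in millimetres from face-adjacency boundary voxels. A
  structure absent from both masks is reported as undefined, never as 0 or 1.

## Worked example

```python
import numpy as np
from scdunet import (PhantomSpec, generate_cohort, cohort_statistics,
                     dsc_pair, dsc_agg, max_receptive_field)

cases = generate_cohort(20, base_seed=42, spec=PhantomSpec())
stats = cohort_statistics(cases)
print(stats["foreground_fraction"].median())   # 0.00173
print(stats["foreground_fraction"].mean())     # 0.00177  (right-skewed)

gt_a = np.zeros(30, bool); gt_a[:10] = True
pr_a = np.zeros(30, bool); pr_a[5:15] = True   # per-case DSC 0.5
gt_b = np.zeros(30, bool); gt_b[:2]  = True    # per-case DSC 1.0
print(dsc_agg([(gt_a, pr_a), (gt_b, gt_b)]))   # 0.5833... = 14/24

print(max_receptive_field(3, (1, 2, 3)))       # 13
```

The cohort statistics show the generator reproducing the right-skewed tumor
voxel fractions (all 20 cases within the 0.000–0.004 band, median below the
mean) and tumor mean intensities inside the 50–100 band. The aggregated DSC
of 14/24 ≈ 0.583 demonstrates pooled-count aggregation: the larger case
dominates, unlike a plain mean of 0.75. The receptive-field value 13 is the
dense pyramid's maximum: branch fields 3/5/7, with the d=3 branch stacked on
the d1→d2 chain (7 + 7 − 1).

Longer narrative scripts live in `examples/`: phantom generation, the
receptive-field algebra, losses/metrics on worked cases, and a toy training
run (`examples/04_toy_training.py`) whose validation mean foreground DSC
climbs to ~0.9 within 30 epochs on 64×64 phantoms.

## Command line

```bash
scdunet generate --n 10 --seed 1 --out data/            # phantom cohort (NIfTI)
scdunet preprocess --in data/ --out prep/ --side 448 --seed 0
scdunet train --config exp.yaml --data prep/ --fold 0 --out runs/f0
scdunet cross-validate --config exp.yaml --data prep/ --out runs/cv
scdunet predict --checkpoint runs/f0/checkpoint.npz --image case_T2.nii.gz --out pred.nii.gz
scdunet evaluate --gt-dir data/ --pred-dir preds/ --out report/
scdunet rf --kernel 3 --dilations 1 --dilations 2 --dilations 3 --stack 2   # prints 13
```

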