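"""Synthetic head-and-neck MRI phantoms.

Generates 3D T2-like intensity volumes with integer tumor masks
(background=0, primary tumor GTVp=1, nodal tumors GTVn=2) whose summary
statistics mirror the cohort the model targets: right-skewed tumor voxel
fractions in the 0.000-0.004 range, tumor-region mean intensities peaking
at 50-100 with standard deviations up to 50, at most one GTVp and a
configurable number of GTVn lesions per case.

Lesions are anisotropic ellipsoids perturbed by smoothed noise and
thresholded, yielding smooth connected blobs.  GTVp is placed near the
in-plane midline (oropharyngeal position) and GTVn lesions laterally
(neck levels), which gives the two classes a positional prior a
segmentation network can exploit — the intensity distributions of the two
classes are deliberately identical.

Everything is driven by a single integer seed: the same spec and seed
reproduce a case bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = ["PhantomSpec", "MriCase", "PhantomGenerationError",
           "generate_case", "generate_cohort", "cohort_statistics",
           "training_preset"]


class PhantomGenerationError(ValueError):
    """Raised when a phantom cannot satisfy the requested constraints."""


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic case.

    Defaults emulate the target cohort at a reduced 64x64x32 grid; pass a
    larger ``volume_shape`` for full-size volumes.
    """

    volume_shape: tuple = (64, 64, 32)
    spacing_mm: tuple = (0.5, 0.5, 2.0)
    gtvp_count: int = 1
    gtvn_count: int = 2
    target_voxel_fraction_range: tuple = (0.0003, 0.004)
    tumor_mean_intensity_range: tuple = (50.0, 100.0)
    tumor_intensity_sd_range: tuple = (0.0, 50.0)
    background_intensity_model: tuple = (35.0, 15.0)
    noise_sd: float = 4.0
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.target_voxel_fraction_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("target_voxel_fraction_range must be ordered within [0, 1]")
        if self.gtvp_count not in (0, 1):
            raise ValueError("gtvp_count must be 0 or 1 (at most one primary tumor)")
        if self.gtvn_count < 0:
            raise ValueError("gtvn_count must be nonnegative")
        for rng_pair in (self.tumor_mean_intensity_range, self.tumor_intensity_sd_range):
            if rng_pair[0] > rng_pair[1]:
                raise ValueError("intensity ranges must be ordered low <= high")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing_mm must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


@dataclass
class MriCase:
    """One patient's volume: intensities, label mask, voxel spacing, id."""

    case_id: str
    volume: np.ndarray      # 3D nonnegative float
    mask: np.ndarray        # 3D int in {0, 1, 2}
    spacing_mm: tuple

    def __post_init__(self):
        self.volume = np.asarray(self.volume)
        self.mask = np.asarray(self.mask)
        if self.volume.shape != self.mask.shape:
            raise ValueError(
                f"volume shape {self.volume.shape} != mask shape {self.mask.shape}")
        labels = np.unique(self.mask)
        if not np.isin(labels, (0, 1, 2)).all():
            raise ValueError(f"mask labels must be in {{0,1,2}}, got {labels}")
        if not np.isfinite(self.volume).all():
            raise ValueError("volume intensities must be finite")

    @property
    def foreground_fraction(self) -> float:
        return float((self.mask > 0).mean())


def training_preset(**overrides) -> PhantomSpec:
    """Phantom spec for toy training runs at the 64x64 test grid.

    Relative lesion size is enlarged compared to the cohort default so that
    a lesion still spans a learnable number of voxels after the 8x
    coarsening of the in-plane grid; boundary voxels then remain a minor
    fraction of the lesion volume.
    """
    params = dict(target_voxel_fraction_range=(0.004, 0.015),
                  gtvn_count=1, tumor_intensity_sd_range=(5.0, 25.0))
    params.update(overrides)
    return PhantomSpec(**params)


def _head_mask(shape) -> np.ndarray:
    nx, ny, nz = shape
    x, y, z = np.ogrid[:nx, :ny, :nz]
    cx, cy, cz = (nx - 1) / 2, (ny - 1) / 2, (nz - 1) / 2
    q = (((x - cx) / (0.45 * nx)) ** 2
         + ((y - cy) / (0.45 * ny)) ** 2
         + ((z - cz) / (0.55 * nz)) ** 2)
    return q <= 1.0


def _lesion_mask(shape, center, semi_axes, rng) -> np.ndarray:
    """Perturbed-ellipsoid binary blob; smooth boundary, connected."""
    nx, ny, nz = shape
    x, y, z = np.ogrid[:nx, :ny, :nz]
    q = (((x - center[0]) / semi_axes[0]) ** 2
         + ((y - center[1]) / semi_axes[1]) ** 2
         + ((z - center[2]) / semi_axes[2]) ** 2)
    field = 1.0 - q
    # low-frequency boundary perturbation, kept small so blobs stay connected
    noise = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=2.0)
    scale = noise.std()
    if scale > 0:
        field = field + 0.25 * noise / scale * np.exp(-np.maximum(q - 1.0, 0.0))
    mask = field > 0.0
    if mask.any():
        # keep the component containing (or nearest) the center
        lab, n = ndimage.label(mask)
        if n > 1:
            target = lab[tuple(np.clip(np.round(center).astype(int), 0, np.array(shape) - 1))]
            if target == 0:
                sizes = ndimage.sum_labels(mask, lab, index=np.arange(1, n + 1))
                target = int(np.argmax(sizes)) + 1
            mask = lab == target
    return mask


def _semi_axes_for_budget(budget_voxels: float, spacing, rng) -> np.ndarray:
    """Ellipsoid semi-axes (voxels) with physical near-isotropy and jitter."""
    aspect = rng.uniform(0.7, 1.4, size=3)
    aniso = np.array([1.0, 1.0, spacing[0] / spacing[2]]) * aspect
    # budget = 4/3 pi * a^3 * prod(aniso)  =>  base radius a
    a = (budget_voxels / (4.0 / 3.0 * np.pi * np.prod(aniso))) ** (1.0 / 3.0)
    return np.maximum(a * aniso, 0.8)


def _place_center(kind: str, shape, rng) -> np.ndarray:
    nx, ny, nz = shape
    cz = rng.uniform(0.30, 0.70) * nz
    if kind == "gtvp":
        cx = nx / 2 + rng.normal(0, 0.04 * nx)
        cy = ny / 2 + rng.normal(0, 0.06 * ny)
    else:  # nodal lesions sit laterally
        side = rng.choice((-1.0, 1.0))
        cx = nx / 2 + side * rng.uniform(0.16, 0.28) * nx
        cy = ny / 2 + rng.normal(0, 0.10 * ny)
    return np.array([cx, cy, cz])


def generate_case(spec: PhantomSpec, seed: int | None = None,
                  case_id: str | None = None) -> MriCase:
    """Generate one phantom case.

    The achieved foreground voxel fraction is driven into
    ``spec.target_voxel_fraction_range`` by iterative radius correction
    (vacuous when the spec requests zero lesions).  Identical spec and
    seed give a bit-identical case.
    """
    seed = spec.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    shape = tuple(spec.volume_shape)
    nvox = int(np.prod(shape))
    lo, hi = spec.target_voxel_fraction_range
    n_lesions = spec.gtvp_count + spec.gtvn_count
    if case_id is None:
        case_id = f"phantom_{seed:05d}"

    head = _head_mask(shape)
    bg_mean, bg_sd = spec.background_intensity_model
    volume = np.where(head, np.abs(rng.normal(bg_mean, bg_sd, shape)), 0.0)
    mask = np.zeros(shape, dtype=np.int16)

    if n_lesions > 0:
        min_feasible = 2.0 * n_lesions / nvox
        if hi < min_feasible:
            raise PhantomGenerationError(
                f"target_voxel_fraction_range {spec.target_voxel_fraction_range} is "
                f"infeasible for shape {shape}: {n_lesions} lesion(s) need at least "
                f"{min_feasible:.2e} of the volume")
        # log-uniform draw -> right-skewed fractions across a cohort
        lo_eff = max(lo, min_feasible)
        target = float(np.exp(rng.uniform(np.log(lo_eff), np.log(hi)))) * nvox

        weights = rng.uniform(0.6, 1.4, size=n_lesions)
        weights /= weights.sum()
        kinds = ["gtvp"] * spec.gtvp_count + ["gtvn"] * spec.gtvn_count
        centers = [_place_center(kind, shape, rng) for kind in kinds]
        axes = [_semi_axes_for_budget(target * w, spec.spacing_mm, rng)
                for w in weights]
        noise_seeds = [int(rng.integers(0, 2 ** 31)) for _ in kinds]

        scale = 1.0
        for _ in range(12):
            mask[:] = 0
            for kind, center, ax, nseed in zip(kinds, centers, axes, noise_seeds):
                blob = _lesion_mask(shape, center, np.maximum(ax * scale, 0.8),
                                    np.random.default_rng(nseed))
                blob &= head
                blob &= mask == 0          # GTVp and GTVn never overlap
                mask[blob] = 1 if kind == "gtvp" else 2
            achieved = (mask > 0).sum()
            if achieved > 0 and lo * nvox <= achieved <= hi * nvox:
                break
            ref = max(achieved, 1)
            scale *= (target / ref) ** (1.0 / 3.0)
            scale = float(np.clip(scale, 0.05, 50.0))
        else:
            raise PhantomGenerationError(
                f"could not reach a foreground fraction in "
                f"{spec.target_voxel_fraction_range} for shape {shape}")

        for label, kind in ((1, "gtvp"), (2, "gtvn")):
            region = mask == label
            if not region.any():
                continue
            t_mean = rng.uniform(*spec.tumor_mean_intensity_range)
            t_sd = rng.uniform(*spec.tumor_intensity_sd_range)
            volume[region] = np.abs(rng.normal(t_mean, t_sd, int(region.sum())))

    if spec.noise_sd > 0:
        volume = np.abs(volume + rng.normal(0, spec.noise_sd, shape) * head)

    return MriCase(case_id=case_id, volume=volume.astype(np.float32),
                   mask=mask, spacing_mm=tuple(spec.spacing_mm))


def generate_cohort(n: int, base_seed: int, spec: PhantomSpec | None = None) -> list:
    """Generate `n` cases with distinct ids; per-case seed = base_seed + index."""
    if n <= 0:
        raise ValueError("n must be >= 1")
    spec = spec if spec is not None else PhantomSpec()
    return [generate_case(spec, seed=base_seed + i, case_id=f"case_{base_seed + i:05d}")
            for i in range(n)]


def cohort_statistics(cases) -> "pandas.DataFrame":
    """Per-case foreground fraction and tumor-region intensity mean/sd.

    Cases with an empty mask report NaN intensity statistics rather than
    raising.
    """
    import pandas as pd

    cases = list(cases)
    if not cases:
        raise ValueError("cohort_statistics requires a nonempty case list")
    rows = []
    for case in cases:
        fg = case.mask > 0
        if fg.any():
            vals = case.volume[fg]
            t_mean, t_sd = float(vals.mean()), float(vals.std())
        else:
            t_mean = t_sd = float("nan")
        rows.append({"case_id": case.case_id,
                     "foreground_fraction": case.foreground_fraction,
                     "tumor_mean_intensity": t_mean,
                     "tumor_intensity_sd": t_sd})
    return pd.DataFrame(rows)
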