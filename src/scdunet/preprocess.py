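"""NIfTI I/O, intensity normalisation, slice handling and fold protocol.

The pipeline mirrors the training protocol of the segmentation study:
z-score normalisation computed over the valid (strictly positive) voxel
region, in-plane resizing to the network resolution (448x448 at full
scale), screening of training slices that contain tumor, and a fixed
partition of the cohort into an independent test set plus five
cross-validation folds.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from skimage.transform import resize

from .phantom import MriCase

__all__ = ["SliceSample", "FoldPlan", "normalize_intensity", "resample_slice",
           "screen_slices", "make_fold_plan", "read_case", "write_case"]

NETWORK_SIDE = 448  # in-plane training resolution at full scale


@dataclass
class SliceSample:
    """One preprocessed 2D image/mask pair at network resolution."""

    case_id: str
    slice_index: int
    image: np.ndarray
    mask: np.ndarray

    def __post_init__(self):
        if self.image.shape != self.mask.shape:
            raise ValueError("image and mask shapes must match")
        if not np.isin(np.unique(self.mask), (0, 1, 2)).all():
            raise ValueError("mask labels must be in {0,1,2}")


@dataclass
class FoldPlan:
    """Independent test ids plus five train/validation folds."""

    test_ids: list
    folds: list            # list of {"train": [...], "val": [...]}
    seed: int

    def to_json(self) -> str:
        return json.dumps({"test": list(self.test_ids),
                           "folds": [{"train": list(f["train"]), "val": list(f["val"])}
                                     for f in self.folds],
                           "seed": self.seed}, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "FoldPlan":
        obj = json.loads(text)
        return cls(test_ids=obj["test"], folds=obj["folds"], seed=obj["seed"])


def normalize_intensity(volume: np.ndarray) -> np.ndarray:
    """Z-score a volume over its valid region (intensity > 0).

    Air/background voxels (<= 0) do not contribute to the statistics and
    are mapped to the minimum normalised value so they stay the darkest
    voxels.  A constant valid region yields zeros there, with a warning.
    """
    volume = np.asarray(volume, dtype=np.float64)
    if not np.isfinite(volume).all():
        raise ValueError("volume must be finite")
    out = np.empty_like(volume)
    valid = volume > 0
    if not valid.any():
        warnings.warn("volume has no valid (positive) voxels; returning zeros")
        return np.zeros_like(volume)
    vals = volume[valid]
    mean, sd = vals.mean(), vals.std()
    if sd == 0:
        warnings.warn("valid region is constant; normalised to zeros")
        normed = np.zeros_like(vals)
    else:
        normed = (vals - mean) / sd
    out[valid] = normed
    out[~valid] = normed.min() if normed.size else 0.0
    return out


def resample_slice(image: np.ndarray, mask: np.ndarray, side: int = NETWORK_SIDE):
    """Resize a 2D image/mask pair to side x side.

    Bilinear interpolation for the image, nearest-neighbour for the mask
    (labels preserved exactly).  Inputs already at the target size are
    returned unchanged.
    """
    image = np.asarray(image)
    mask = np.asarray(mask)
    if image.size == 0 or mask.size == 0:
        raise ValueError("empty slice")
    if image.shape != mask.shape:
        raise ValueError(f"image shape {image.shape} != mask shape {mask.shape}")
    if image.shape == (side, side):
        return image, mask
    img_out = resize(image.astype(np.float64), (side, side), order=1,
                     preserve_range=True, anti_aliasing=False)
    mask_out = resize(mask, (side, side), order=0, preserve_range=True,
                      anti_aliasing=False).astype(mask.dtype)
    return img_out, mask_out


def screen_slices(case: MriCase) -> list:
    """Axial slice indices (third axis) whose mask has >= 1 tumor voxel.

    Used on training data only; validation and test volumes are evaluated
    in full to avoid label leakage.
    """
    nonzero = (case.mask > 0).any(axis=(0, 1))
    return [int(i) for i in np.flatnonzero(nonzero)]


def make_fold_plan(case_ids, seed: int) -> FoldPlan:
    """Shuffle ids and build the test/five-fold partition.

    A third of the ids (rounded down) form the independent test set; the
    remainder is split into five disjoint validation blocks, each fold
    training on the other four blocks.  With 150 ids this reproduces the
    50 / (80 train + 20 val) protocol.
    """
    ids = list(case_ids)
    if len(ids) != len(set(ids)):
        raise ValueError("case ids must be unique")
    if len(ids) < 10:
        raise ValueError(f"need at least 10 ids to build 5 folds, got {len(ids)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    shuffled = [ids[i] for i in order]
    n_test = len(ids) // 3
    test_ids = shuffled[:n_test]
    rest = shuffled[n_test:]
    blocks = [list(b) for b in np.array_split(np.array(rest, dtype=object), 5)]
    folds = []
    for k in range(5):
        val = [str(x) for x in blocks[k]]
        train = [str(x) for b in blocks[:k] + blocks[k + 1:] for x in b]
        folds.append({"train": train, "val": val})
    return FoldPlan(test_ids=[str(x) for x in test_ids], folds=folds, seed=seed)


def _affine(spacing_mm) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing_mm
    return aff


def write_case(case: MriCase, out_dir) -> tuple:
    """Write `<id>_T2.nii.gz` and `<id>_mask.nii.gz`; returns both paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    img_path = out_dir / f"{case.case_id}_T2.nii.gz"
    mask_path = out_dir / f"{case.case_id}_mask.nii.gz"
    aff = _affine(case.spacing_mm)
    nib.save(nib.Nifti1Image(case.volume.astype(np.float32), aff), img_path)
    nib.save(nib.Nifti1Image(case.mask.astype(np.int16), aff), mask_path)
    return img_path, mask_path


def read_case(image_path, mask_path, case_id: str | None = None) -> MriCase:
    """Read a paired intensity/mask NIfTI into an MriCase.

    Round-trips with :func:`write_case`: voxel values, labels and spacing
    are preserved.  Shape mismatches and out-of-contract labels raise.
    """
    image_path, mask_path = Path(image_path), Path(mask_path)
    img = nib.load(image_path)
    msk = nib.load(mask_path)
    vol = np.asarray(img.dataobj, dtype=np.float32)
    mask = np.asarray(msk.dataobj).astype(np.int16)
    if vol.shape != mask.shape:
        raise ValueError(
            f"image shape {vol.shape} does not match mask shape {mask.shape}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    if case_id is None:
        case_id = image_path.name.replace("_T2.nii.gz", "").replace(".nii.gz", "")
    return MriCase(case_id=case_id, volume=vol, mask=mask, spacing_mm=spacing)
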