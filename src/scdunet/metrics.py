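"""Segmentation evaluation: DSC, aggregated DSC, Hausdorff and HD95.

Per-structure (GTVp = label 1, GTVn = label 2) Dice overlap and
95th-percentile Hausdorff distance in millimetres, with an explicit
"undefined" policy: when a structure is absent from both ground truth and
prediction the DSC is uninformative and is reported as ``None`` (excluded
from averages but counted), never substituted with 0 or 1.  The
aggregated DSC pools voxel counts across cases before taking the ratio,
which is the robust answer to empty ground-truth structures.

HD95 uses pooled bidirectional boundary-to-boundary distances (boundary =
foreground voxel with a face-adjacent neighbour of different value),
computed in physical units via the voxel spacing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

__all__ = ["dsc_pair", "dsc_agg", "hausdorff", "hd95", "boundary_points",
           "evaluate_volume", "MetricReport", "STRUCTURES"]

STRUCTURES = {"GTVp": 1, "GTVn": 2}

_FACE_STRUCTURE = {
    2: ndimage.generate_binary_structure(2, 1),
    3: ndimage.generate_binary_structure(3, 1),
}


def dsc_pair(gt: np.ndarray, pred: np.ndarray):
    """Dice coefficient 2|A∩B| / (|A|+|B|); None when both masks are empty."""
    gt = np.asarray(gt).astype(bool)
    pred = np.asarray(pred).astype(bool)
    if gt.shape != pred.shape:
        raise ValueError(f"shape mismatch: {gt.shape} vs {pred.shape}")
    denom = int(gt.sum()) + int(pred.sum())
    if denom == 0:
        return None
    return 2.0 * int((gt & pred).sum()) / denom


def dsc_agg(cases):
    """Aggregated DSC: pool intersections and sizes across cases first.

    `cases` is an iterable of (gt, pred) binary mask pairs.  Returns None
    if every mask in the pool is empty.
    """
    cases = list(cases)
    if not cases:
        raise ValueError("dsc_agg needs at least one case")
    inter = 0
    sizes = 0
    for gt, pred in cases:
        gt = np.asarray(gt).astype(bool)
        pred = np.asarray(pred).astype(bool)
        if gt.shape != pred.shape:
            raise ValueError(f"shape mismatch: {gt.shape} vs {pred.shape}")
        inter += int((gt & pred).sum())
        sizes += int(gt.sum()) + int(pred.sum())
    if sizes == 0:
        return None
    return 2.0 * inter / sizes


def hausdorff(gt_points, pred_points, spacing_mm=None):
    """Symmetric Hausdorff distance between two point sets, in mm.

    max{ h(P,Q), h(Q,P) } with h the directed max-min Euclidean distance.
    Points are voxel coordinates; `spacing_mm` scales each axis to
    millimetres (identity if omitted).  Returns None if either set is
    empty.
    """
    p = np.atleast_2d(np.asarray(gt_points, dtype=float))
    q = np.atleast_2d(np.asarray(pred_points, dtype=float))
    if p.size == 0 or q.size == 0:
        return None
    if spacing_mm is not None:
        spacing = np.asarray(spacing_mm, dtype=float)
        p = p * spacing
        q = q * spacing
    d_pq = cKDTree(q).query(p)[0].max()
    d_qp = cKDTree(p).query(q)[0].max()
    return float(max(d_pq, d_qp))


def boundary_points(mask: np.ndarray) -> np.ndarray:
    """Voxel coordinates of foreground voxels with a face-adjacent
    neighbour of different value (array edges count as background)."""
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        return np.empty((0, mask.ndim))
    eroded = ndimage.binary_erosion(mask, structure=_FACE_STRUCTURE[mask.ndim],
                                    border_value=0)
    return np.argwhere(mask & ~eroded).astype(float)


def _directed_surface_distances(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    return cKDTree(q).query(p)[0]


def hd95(gt_mask, pred_mask, spacing_mm):
    """95th percentile of pooled bidirectional boundary distances, in mm.

    Returns None when either mask is empty.  Linear in the voxel spacing:
    doubling every spacing component doubles the result exactly.
    """
    gt_mask = np.asarray(gt_mask).astype(bool)
    pred_mask = np.asarray(pred_mask).astype(bool)
    if gt_mask.shape != pred_mask.shape:
        raise ValueError(f"shape mismatch: {gt_mask.shape} vs {pred_mask.shape}")
    if not gt_mask.any() or not pred_mask.any():
        return None
    spacing = np.asarray(spacing_mm, dtype=float)
    if (spacing <= 0).any():
        raise ValueError("spacing must be positive")
    p = boundary_points(gt_mask) * spacing
    q = boundary_points(pred_mask) * spacing
    dists = np.concatenate([_directed_surface_distances(p, q),
                            _directed_surface_distances(q, p)])
    return float(np.percentile(dists, 95))


@dataclass
class MetricReport:
    """Per-case rows plus pooled aggregates."""

    rows: list          # dicts: case_id, structure, dsc, hd95_mm (None = undefined)

    def to_frame(self) -> "pandas.DataFrame":
        import pandas as pd
        return pd.DataFrame(self.rows, columns=["case_id", "structure", "dsc", "hd95_mm"])

    def mean_dsc(self):
        vals = [r["dsc"] for r in self.rows if r["dsc"] is not None]
        return float(np.mean(vals)) if vals else None

    def mean_hd95(self):
        vals = [r["hd95_mm"] for r in self.rows if r["hd95_mm"] is not None]
        return float(np.mean(vals)) if vals else None

    def undefined_counts(self) -> dict:
        return {"dsc": sum(r["dsc"] is None for r in self.rows),
                "hd95_mm": sum(r["hd95_mm"] is None for r in self.rows)}

    def summary(self, gt_pred_pairs=None) -> dict:
        """JSON-ready per-structure summary; aggregated DSC needs the
        original (gt, pred, spacing) triples via `gt_pred_pairs`."""
        out = {}
        for name in STRUCTURES:
            rows = [r for r in self.rows if r["structure"] == name]
            dscs = [r["dsc"] for r in rows if r["dsc"] is not None]
            hds = [r["hd95_mm"] for r in rows if r["hd95_mm"] is not None]
            entry = {"dsc_mean": float(np.mean(dscs)) if dscs else None,
                     "hd95_mean": float(np.mean(hds)) if hds else None}
            if gt_pred_pairs is not None:
                label = STRUCTURES[name]
                entry["dsc_agg"] = dsc_agg(
                    [(gt == label, pred == label) for gt, pred, _ in gt_pred_pairs])
            out[name] = entry
        defined = [v for k in out for v in [out[k].get("dsc_agg", out[k]["dsc_mean"])]
                   if v is not None]
        out["avg"] = {"dsc": float(np.mean(defined)) if defined else None,
                      "hd95": self.mean_hd95()}
        return out


def evaluate_volume(gt: np.ndarray, pred: np.ndarray, spacing_mm,
                    case_id: str = "case") -> list:
    """Per-structure DSC and HD95 rows for one case.

    Labels outside {0,1,2} are a contract violation and raise.
    """
    gt = np.asarray(gt)
    pred = np.asarray(pred)
    if gt.shape != pred.shape:
        raise ValueError(f"shape mismatch: {gt.shape} vs {pred.shape}")
    for name, arr in (("ground truth", gt), ("prediction", pred)):
        labels = np.unique(arr)
        if not np.isin(labels, (0, 1, 2)).all():
            raise ValueError(f"{name} contains labels outside {{0,1,2}}: {labels}")
    rows = []
    for structure, label in STRUCTURES.items():
        g = gt == label
        p = pred == label
        rows.append({"case_id": case_id, "structure": structure,
                     "dsc": dsc_pair(g, p), "hd95_mm": hd95(g, p, spacing_mm)})
    return rows
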