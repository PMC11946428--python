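"""Segmentation evaluation: overlap, surface-distance and volume metrics,
per-lesion size measurement, and the Dice-stratified size analysis.

Conventions
-----------
* Dice(A, B) = 2|A n B| / (|A| + |B|); 1 when both masks are empty.
* Surfaces are mask voxels with at least one 6-connected neighbor outside
  the mask (the grid border counts as outside); surface points live at voxel
  centers scaled by the spacing, so all distances are Euclidean mm.
* ASD averages the directed point-to-surface distances in both directions,
  normalized by the total number of surface points; undefined (error) for
  empty masks.
* RVD(A, B) = (|B| - |A|) / |A| with A the prediction.
* Lesions are 26-connected components; the "major-axis length" of a lesion
  is its Feret diameter (maximum pairwise distance between surface points).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull
from scipy.spatial.distance import pdist

from .grids import Mask

__all__ = ["ConfusionCounts", "SurfaceSet", "SegMetrics", "confusion_counts",
           "dice_score", "extract_surface", "asd", "rvd", "precision_recall",
           "evaluate_masks", "major_axis_length", "stratify_cases"]

_CONN26 = np.ones((3, 3, 3), dtype=bool)


def _grids(a, b=None):
    ga = a.voxels.astype(bool) if isinstance(a, Mask) else np.asarray(a).astype(bool)
    if b is None:
        return ga
    gb = b.voxels.astype(bool) if isinstance(b, Mask) else np.asarray(b).astype(bool)
    if ga.shape != gb.shape:
        raise ValueError(f"shape mismatch: {ga.shape} vs {gb.shape}")
    return ga, gb


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self):
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class SurfaceSet:
    """Boundary voxels of a mask: integer indices and mm coordinates."""

    indices: np.ndarray       # (N, 3) voxel indices
    points_mm: np.ndarray     # (N, 3) spacing-scaled coordinates
    spacing: tuple


@dataclass
class SegMetrics:
    dice: float
    asd_mm: float
    rvd: float
    precision: float
    recall: float


def confusion_counts(pred, truth) -> ConfusionCounts:
    a, b = _grids(pred, truth)
    tp = int(np.count_nonzero(a & b))
    fp = int(np.count_nonzero(a & ~b))
    fn = int(np.count_nonzero(~a & b))
    tn = a.size - tp - fp - fn
    return ConfusionCounts(tp, fp, fn, tn)


def dice_score(pred, truth) -> float:
    a, b = _grids(pred, truth)
    na, nb = int(a.sum()), int(b.sum())
    if na == 0 and nb == 0:
        return 1.0
    inter = int(np.count_nonzero(a & b))
    return 2.0 * inter / (na + nb)


def extract_surface(mask, spacing=None) -> SurfaceSet:
    """Boundary voxels under 6-connectivity with the grid border outside."""
    if isinstance(mask, Mask) and spacing is None:
        spacing = mask.spacing
    g = _grids(mask)
    if spacing is None:
        spacing = (1.0, 1.0, 1.0)
    if not g.any():
        raise ValueError("surface of an empty mask is undefined")
    interior = ndimage.binary_erosion(g)  # border-value 0: edge voxels erode
    surf = g & ~interior
    idx = np.argwhere(surf)
    return SurfaceSet(indices=idx,
                      points_mm=idx * np.asarray(spacing, dtype=float),
                      spacing=tuple(float(s) for s in spacing))


def asd(pred, truth, spacing=None) -> float:
    """Average symmetric surface distance in mm.

    Distances to the nearest surface voxel center are read from an exact
    Euclidean distance transform, which agrees with the brute-force
    all-pairs minimum to floating-point precision.
    """
    if isinstance(pred, Mask) and spacing is None:
        spacing = pred.spacing
    a, b = _grids(pred, truth)
    spacing = (1.0, 1.0, 1.0) if spacing is None else tuple(spacing)
    sa = extract_surface(a, spacing)
    sb = extract_surface(b, spacing)

    def directed_sum(src: SurfaceSet, dst: SurfaceSet) -> float:
        dst_map = np.ones(a.shape, dtype=bool)
        dst_map[tuple(dst.indices.T)] = False
        dt = ndimage.distance_transform_edt(dst_map, sampling=spacing)
        return float(dt[tuple(src.indices.T)].sum())

    total = directed_sum(sa, sb) + directed_sum(sb, sa)
    return total / (len(sa.indices) + len(sb.indices))


def rvd(pred, truth) -> float:
    a, b = _grids(pred, truth)
    na = int(a.sum())
    if na == 0:
        raise ValueError("relative volume difference undefined for an empty "
                         "prediction")
    return (int(b.sum()) - na) / na


def precision_recall(pred, truth) -> tuple:
    c = confusion_counts(pred, truth)
    prec = c.tp / (c.tp + c.fp) if (c.tp + c.fp) else 0.0
    rec = c.tp / (c.tp + c.fn) if (c.tp + c.fn) else 0.0
    return prec, rec


def evaluate_masks(pred, truth, spacing=None) -> SegMetrics:
    """All five per-case metrics for one prediction/ground-truth pair."""
    prec, rec = precision_recall(pred, truth)
    return SegMetrics(dice=dice_score(pred, truth),
                      asd_mm=asd(pred, truth, spacing),
                      rvd=rvd(pred, truth),
                      precision=prec, recall=rec)


def _feret(points: np.ndarray) -> float:
    if len(points) == 1:
        return 0.0
    if len(points) > 32:
        try:  # hull vertices suffice for the diameter
            hull = ConvexHull(points)
            points = points[hull.vertices]
        except Exception:  # degenerate (coplanar/collinear) point sets
            pass
    return float(pdist(points).max())


def major_axis_length(mask, spacing=None) -> list:
    """Feret diameter in mm of every 26-connected lesion (possibly empty)."""
    if isinstance(mask, Mask) and spacing is None:
        spacing = mask.spacing
    g = _grids(mask)
    spacing = (1.0, 1.0, 1.0) if spacing is None else tuple(spacing)
    labels, n = ndimage.label(g, structure=_CONN26)
    out = []
    for i in range(1, n + 1):
        comp = labels == i
        surf = extract_surface(comp, spacing)
        out.append(_feret(surf.points_mm))
    return out


def stratify_cases(cases, threshold: float = 0.6) -> dict:
    """Partition cases into high (Dice >= threshold) and low performance
    groups and average their lesion major-axis lengths.

    ``cases`` is an iterable of mappings with keys ``dice`` and ``lengths``
    (a list of per-lesion mm lengths).  Returns group sizes and mean lengths
    (nan for an empty group).
    """
    high, low = [], []
    for case in cases:
        (high if case["dice"] >= threshold else low).append(case)

    def group(cs):
        lengths = [l for c in cs for l in c["lengths"]]
        return {"n_cases": len(cs),
                "mean_major_axis_mm":
                    float(np.mean(lengths)) if lengths else float("nan")}

    return {"threshold": threshold, "high": group(high), "low": group(low)}
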