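"""Two-stage inference: liver localization, ROI-restricted tumor
segmentation, post-processing, and restoration to the original image grid.

Stage 1 segments the liver on the preprocessed volume; the largest
26-connected component removes false-positive islands.  Stage 2 runs the
tumor network only inside the liver bounding box (expanded by a margin) and
its output is clamped to the stage-1 liver mask, making the anatomical
containment tumor <= liver an enforced invariant.  Both masks are restored
to the original grid through the preprocessing record and composed into a
0/1/2 label map.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.special import expit

from .grids import Mask, PreprocessRecord, Volume
from .nn import Tensor, no_grad
from . import preprocess as pp

__all__ = ["CascadeResult", "largest_component", "liver_roi",
           "mask_normalize_roi", "sliding_window_predict",
           "two_stage_predict"]

_CONN26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class CascadeResult:
    liver: Mask               # original grid
    tumor: Mask               # original grid, subset of liver
    label_map: np.ndarray     # 0 background / 1 liver / 2 tumor
    record: PreprocessRecord
    empty_liver: bool = False

    def __post_init__(self):
        t, l = self.tumor.voxels, self.liver.voxels
        if np.any(t > l):
            raise ValueError("containment violated: tumor outside liver")


def mask_normalize_roi(grid: np.ndarray, liver: np.ndarray) -> np.ndarray:
    """Stage-2 input conditioning: confine to the liver region and z-score.

    Intensities inside the liver mask are standardized by the mask's own
    mean and standard deviation (so the subtle tumor/liver contrast becomes
    order-one); voxels outside the mask are zero.  Used identically with
    the ground-truth liver during training and the predicted liver at
    inference.
    """
    liver = np.asarray(liver) > 0
    out = np.zeros(grid.shape, dtype=np.float32)
    vals = grid[liver].astype(np.float32)
    if vals.size == 0:
        return out
    sd = float(vals.std())
    out[liver] = (vals - float(vals.mean())) / (sd if sd > 1e-6 else 1.0)
    return out


def largest_component(mask, connectivity: int = 26):
    """Keep only the most populous connected component (empty in, empty out)."""
    grid = mask.voxels if isinstance(mask, Mask) else np.asarray(mask)
    structure = _CONN26 if connectivity == 26 else None
    labels, n = ndimage.label(grid > 0, structure=structure)
    if n <= 1:
        out = (grid > 0).astype(np.uint8)
    else:
        sizes = ndimage.sum_labels(grid > 0, labels,
                                   index=np.arange(1, n + 1))
        out = (labels == 1 + int(np.argmax(sizes))).astype(np.uint8)
    if isinstance(mask, Mask):
        return Mask(out, mask.spacing)
    return out


def liver_roi(liver: Mask, margin_vox: int = 10):
    """Bounding box (lo, hi half-open) around the liver plus margin,
    clipped to the grid."""
    if liver.count() == 0:
        raise ValueError("liver mask is empty; no ROI to extract")
    idx = np.argwhere(liver.voxels > 0)
    lo = np.maximum(idx.min(axis=0) - margin_vox, 0)
    hi = np.minimum(idx.max(axis=0) + 1 + margin_vox, liver.shape)
    return tuple(lo), tuple(hi)


def _pad_to(grid: np.ndarray, target):
    pads = [(0, max(0, t - s)) for s, t in zip(grid.shape, target)]
    if any(p[1] for p in pads):
        return np.pad(grid, pads), True
    return grid, False


def sliding_window_predict(model, volume, patch_size=(64, 64, 32),
                           overlap: float = 0.5) -> np.ndarray:
    """Probability grid over a (possibly large) volume by tiled prediction.

    Patches overlap by the given fraction and their sigmoid outputs are
    averaged uniformly; volumes smaller than the patch are zero-padded and
    cropped back.  Deterministic for fixed weights and tiling.
    """
    grid = volume.voxels if isinstance(volume, Volume) else np.asarray(volume)
    orig_shape = grid.shape
    grid, _ = _pad_to(grid.astype(np.float32), patch_size)
    acc = np.zeros(grid.shape, dtype=np.float32)
    cnt = np.zeros(grid.shape, dtype=np.float32)
    steps = [max(1, int(round(p * (1 - overlap)))) for p in patch_size]
    starts = [list(range(0, max(s - p, 0) + 1, st)) or [0]
              for s, p, st in zip(grid.shape, patch_size, steps)]
    # make sure the far edge is covered
    for ax, (s, p) in enumerate(zip(grid.shape, patch_size)):
        last = s - p
        if starts[ax][-1] != last:
            starts[ax].append(last)
    model.eval()
    for x0 in starts[0]:
        for y0 in starts[1]:
            for z0 in starts[2]:
                sl = (slice(x0, x0 + patch_size[0]),
                      slice(y0, y0 + patch_size[1]),
                      slice(z0, z0 + patch_size[2]))
                patch = grid[sl][None, None]
                with no_grad():
                    logits = model(Tensor(patch))
                prob = expit(logits.data[0, 0])
                acc[sl] += prob
                cnt[sl] += 1.0
    out = acc / cnt
    return out[:orig_shape[0], :orig_shape[1], :orig_shape[2]]


def two_stage_predict(liver_model, tumor_model, raw: Volume,
                      threshold: float = 0.5, roi_margin: int = 10,
                      patch_size=(64, 64, 32), overlap: float = 0.5,
                      inplane_factor: float = 0.5,
                      crop_margin: int = 5) -> CascadeResult:
    """Full cascade on a raw HU volume; returns masks in original space."""
    if raw.intensity_kind != "HU":
        raise ValueError("two_stage_predict expects a raw HU volume")
    norm, record = pp.preprocess_case(raw, margin_vox=crop_margin,
                                      inplane_factor=inplane_factor)
    spacing = norm.spacing

    liver_prob = sliding_window_predict(liver_model, norm, patch_size, overlap)
    liver = Mask((liver_prob >= threshold).astype(np.uint8), spacing)
    liver = largest_component(liver)

    if liver.count() == 0:
        empty = Mask(np.zeros(record.original_shape, np.uint8),
                     record.original_spacing)
        return CascadeResult(liver=empty, tumor=empty,
                             label_map=np.zeros(record.original_shape,
                                                np.uint8),
                             record=record, empty_liver=True)

    lo, hi = liver_roi(liver, roi_margin)
    sl = tuple(slice(l, h) for l, h in zip(lo, hi))
    # stage 2 sees liver tissue only, standardized within the liver mask,
    # mirroring the tumor-stage training inputs
    roi_grid = mask_normalize_roi(norm.voxels[sl], liver.voxels[sl])
    tumor_prob_roi = sliding_window_predict(tumor_model, roi_grid,
                                            patch_size, overlap)
    tumor_grid = np.zeros_like(liver.voxels)
    tumor_grid[sl] = (tumor_prob_roi >= threshold).astype(np.uint8)
    tumor_grid &= liver.voxels          # confinement to the liver region
    tumor = Mask(tumor_grid, spacing)

    liver_full = pp.restore_to_original(liver, record)
    tumor_full = pp.restore_to_original(tumor, record)
    tumor_full.voxels &= liver_full.voxels   # containment survives restore
    label_map = liver_full.voxels.astype(np.uint8).copy()
    label_map[tumor_full.voxels > 0] = 2
    return CascadeResult(liver=liver_full, tumor=tumor_full,
                         label_map=label_map, record=record)
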