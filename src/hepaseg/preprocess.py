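"""CT preprocessing: body-mask extraction, cropping, in-plane resampling,
HU windowing — and the exact inverse geometry for mapping predictions back
into the original image space.

Pipeline (forward): threshold + morphology produce a body mask; the volume
is cropped to the body bounding box (plus margin); the x and y axes are
rescaled by a fixed in-plane factor (default 0.5, z untouched) with spacing
updated so the physical extent is preserved; intensities are clipped to the
[-200, 200] HU window and mapped affinely to [0, 1].  A
:class:`~hepaseg.grids.PreprocessRecord` captures the crop box and scale so
masks predicted in the processed grid can be restored voxel-exactly to the
original grid shape.
"""
from __future__ import annotations

import os

import nibabel as nib
import numpy as np
from scipy import ndimage

from .grids import Mask, PreprocessRecord, Volume

__all__ = ["compute_body_mask", "crop_to_body", "resample_inplane",
           "window_normalize", "restore_to_original", "read_case",
           "write_mask", "preprocess_case", "BODY_HU_THRESHOLD",
           "HU_WINDOW"]

BODY_HU_THRESHOLD = -300.0
HU_WINDOW = (-200.0, 200.0)


def compute_body_mask(volume: Volume, threshold: float = BODY_HU_THRESHOLD,
                      closing_radius: int = 3) -> Mask:
    """Patient-body mask from an HU volume.

    Threshold above ``threshold`` HU, close small gaps with a spherical
    structuring element, fill internal holes slice-wise (axial planes), and
    keep the largest 26-connected component, which yields one connected
    body region with the surrounding air excluded.
    """
    if volume.intensity_kind != "HU":
        raise ValueError("body mask requires HU intensities")
    fg = volume.voxels > threshold
    if not fg.any():
        raise ValueError(f"no voxel above {threshold} HU: empty body")
    if closing_radius > 0:
        r = closing_radius
        zz, yy, xx = np.mgrid[-r:r + 1, -r:r + 1, -r:r + 1]
        ball = xx ** 2 + yy ** 2 + zz ** 2 <= r ** 2
        # closing with the correct border semantics: dilation sees air
        # outside the grid, erosion sees tissue (so a body touching the
        # grid edge is not eaten away)
        fg = ndimage.binary_erosion(
            ndimage.binary_dilation(fg, structure=ball),
            structure=ball, border_value=1)
    # slice-wise hole filling along z (axial planes)
    for k in range(fg.shape[2]):
        fg[:, :, k] = ndimage.binary_fill_holes(fg[:, :, k])
    labels, n = ndimage.label(fg, structure=np.ones((3, 3, 3), bool))
    if n > 1:
        sizes = ndimage.sum_labels(fg, labels, index=np.arange(1, n + 1))
        fg = labels == (1 + int(np.argmax(sizes)))
    return Mask(fg.astype(np.uint8), volume.spacing)


def crop_to_body(volume: Volume, body: Mask, margin_vox: int = 5):
    """Crop to the body bounding box expanded by ``margin_vox`` (clipped to
    the grid); returns the cropped volume and the geometry record."""
    if body.count() == 0:
        raise ValueError("cannot crop to an empty body mask")
    if body.shape != volume.shape:
        raise ValueError("body mask shape differs from volume shape")
    idx = np.argwhere(body.voxels > 0)
    lo = np.maximum(idx.min(axis=0) - margin_vox, 0)
    hi = np.minimum(idx.max(axis=0) + 1 + margin_vox, volume.shape)
    record = PreprocessRecord(original_shape=volume.shape,
                              original_spacing=volume.spacing,
                              crop_lo=tuple(lo), crop_hi=tuple(hi))
    sl = tuple(slice(l, h) for l, h in zip(lo, hi))
    cropped = Volume(volume.voxels[sl].copy(), volume.spacing,
                     volume.intensity_kind)
    return cropped, record


def _scaled_dims(shape, factor):
    return (max(1, round(shape[0] * factor)),
            max(1, round(shape[1] * factor)), shape[2])


def resample_inplane(volume, factor: float = 0.5, is_mask: bool = False):
    """Rescale the x and y axes by ``factor`` (z untouched).

    Trilinear interpolation for intensities, nearest-neighbor for masks;
    the spacing is updated so dim * spacing (physical extent) is preserved
    up to the rounding of the new dimension.
    """
    if factor <= 0:
        raise ValueError("resampling factor must be positive")
    if factor > 1:
        raise ValueError("in-plane resampling only downscales (factor <= 1)")
    grid = volume.voxels
    new_dims = _scaled_dims(grid.shape, factor)
    if new_dims == grid.shape:
        return volume
    zoom = [n / o for n, o in zip(new_dims, grid.shape)]
    order = 0 if is_mask else 1
    out = ndimage.zoom(grid.astype(np.float32), zoom, order=order,
                       mode="nearest", grid_mode=True)
    out = out[:new_dims[0], :new_dims[1], :new_dims[2]]
    new_spacing = tuple(s * o / n for s, o, n in
                        zip(volume.spacing, grid.shape, new_dims))
    if is_mask:
        return Mask((out > 0.5).astype(np.uint8), new_spacing)
    return Volume(out, new_spacing, volume.intensity_kind)


def window_normalize(volume: Volume, window: tuple = HU_WINDOW,
                     mode: str = "unit") -> Volume:
    """Clip to the HU window and map to [0, 1].

    ``mode='unit'`` (default): (clip(v, lo, hi) - lo) / (hi - lo).
    ``mode='symmetric'``: clip(v, lo, hi) / hi, giving [-1, 1] for a
    symmetric window (the alternative reading of a divide-by-200
    normalization).
    Already-normalized input is returned unchanged (idempotence).
    """
    if volume.intensity_kind == "normalized":
        return volume
    lo, hi = window
    v = np.clip(volume.voxels.astype(np.float32), lo, hi)
    if mode == "unit":
        out = (v - lo) / (hi - lo)
    elif mode == "symmetric":
        out = v / hi
        return Volume(out, volume.spacing, "HU")  # not in [0,1]; keep kind
    else:
        raise ValueError("mode must be 'unit' or 'symmetric'")
    return Volume(out, volume.spacing, "normalized")


def restore_to_original(mask: Mask, record: PreprocessRecord) -> Mask:
    """Map a mask from the processed grid back to the original grid.

    Nearest-neighbor rescale to the crop-box shape, then paste at the crop
    offset into a zero grid of the original shape.
    """
    if tuple(mask.shape) != tuple(record.processed_shape):
        raise ValueError(
            f"mask shape {mask.shape} does not match the processed shape "
            f"{record.processed_shape} implied by the record")
    crop_shape = record.crop_shape
    grid = mask.voxels
    if mask.shape != crop_shape:
        zoom = [c / m for c, m in zip(crop_shape, mask.shape)]
        grid = ndimage.zoom(grid, zoom, order=0, mode="nearest",
                            grid_mode=True)
        grid = grid[:crop_shape[0], :crop_shape[1], :crop_shape[2]]
    full = np.zeros(record.original_shape, dtype=np.uint8)
    sl = tuple(slice(l, h) for l, h in zip(record.crop_lo, record.crop_hi))
    full[sl] = grid
    return Mask(full, record.original_spacing)


def preprocess_case(volume: Volume, margin_vox: int = 5,
                    inplane_factor: float = 0.5,
                    labels: np.ndarray | None = None,
                    window: tuple = HU_WINDOW):
    """Full forward pipeline; returns (normalized volume, record[, labels])."""
    body = compute_body_mask(volume)
    cropped, record = crop_to_body(volume, body, margin_vox)
    record.inplane_scale = inplane_factor
    resampled = resample_inplane(cropped, inplane_factor)
    normalized = window_normalize(resampled, window=window)
    if labels is None:
        return normalized, record
    lab_crop = labels[tuple(slice(l, h) for l, h in
                            zip(record.crop_lo, record.crop_hi))]
    lab = ndimage.zoom(lab_crop, [n / o for n, o in
                                  zip(normalized.shape, lab_crop.shape)],
                       order=0, mode="nearest", grid_mode=True)
    lab = lab[:normalized.shape[0], :normalized.shape[1], :normalized.shape[2]]
    return normalized, record, lab.astype(np.uint8)


# ---------------------------------------------------------------------------
# NIfTI I/O (LiTS conventions: volume-{i}.nii[.gz] / segmentation-{i}.nii[.gz],
# labels 0 background / 1 liver / 2 tumor)
# ---------------------------------------------------------------------------

def read_case(path, label_path=None):
    """Read an intensity volume (and optional label grid) from NIfTI.

    Spacing is taken from the header; labels outside {0, 1, 2} raise.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D image, got {data.ndim}D")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    volume = Volume(data.astype(np.float32), spacing, "HU")
    if label_path is None:
        return volume, None
    limg = nib.load(str(label_path))
    lab = np.asanyarray(limg.dataobj)
    if lab.ndim != 3:
        raise ValueError(f"{label_path}: expected a 3D label image")
    if lab.shape != data.shape:
        raise ValueError("label grid shape differs from volume shape")
    bad = np.setdiff1d(np.unique(lab), [0, 1, 2])
    if bad.size:
        raise ValueError(f"unexpected label values {bad.tolist()}; "
                         "expected 0 (background), 1 (liver), 2 (tumor)")
    return volume, lab.astype(np.uint8)


def write_volume(volume: Volume, path) -> None:
    affine = np.diag(list(volume.spacing) + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(volume.voxels), affine), str(path))


def write_labels(labels: np.ndarray, spacing, path) -> None:
    bad = np.setdiff1d(np.unique(labels), [0, 1, 2])
    if bad.size:
        raise ValueError(f"unexpected label values {bad.tolist()}")
    affine = np.diag(list(spacing) + [1.0])
    nib.save(nib.Nifti1Image(labels.astype(np.uint8), affine), str(path))


def write_mask(mask: Mask, record: PreprocessRecord | None, path) -> None:
    """Write a mask as NIfTI, restoring to original space when a record is
    given."""
    out = restore_to_original(mask, record) if record is not None else mask
    affine = np.diag(list(out.spacing) + [1.0])
    nib.save(nib.Nifti1Image(out.voxels, affine), str(path))
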