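"""Core data containers: intensity volumes, binary masks, and the invertible
preprocessing geometry record."""
from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

__all__ = ["Volume", "Mask", "PreprocessRecord"]


@dataclass
class Volume:
    """A dense 3D scalar grid with voxel spacing in mm, axes ordered (x, y, z).

    ``intensity_kind`` is "HU" for calibrated CT values or "normalized" for
    windowed intensities in [0, 1].
    """

    voxels: np.ndarray
    spacing: tuple
    intensity_kind: str = "HU"

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError("volume grid must be 3-dimensional")
        if any(d < 1 for d in self.voxels.shape):
            raise ValueError("grid dimensions must be >= 1")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be three positive mm values")
        if self.intensity_kind not in ("HU", "normalized"):
            raise ValueError("intensity_kind must be 'HU' or 'normalized'")
        if self.intensity_kind == "normalized":
            lo, hi = float(self.voxels.min()), float(self.voxels.max())
            if lo < -1e-6 or hi > 1 + 1e-6:
                raise ValueError("normalized intensities must lie in [0, 1]")

    @property
    def shape(self):
        return self.voxels.shape


@dataclass
class Mask:
    """A binary 3D grid aligned with a :class:`Volume`."""

    voxels: np.ndarray
    spacing: tuple

    def __post_init__(self):
        v = np.asarray(self.voxels)
        if v.ndim != 3:
            raise ValueError("mask grid must be 3-dimensional")
        uniq = np.unique(v)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError("mask values must be 0 or 1")
        self.voxels = v.astype(np.uint8)
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be three positive mm values")

    @property
    def shape(self):
        return self.voxels.shape

    def count(self) -> int:
        return int(self.voxels.sum())


@dataclass
class PreprocessRecord:
    """Invertible geometry of preprocessing: the retained crop box (0-based,
    half-open) in the original grid and the in-plane scale factor applied to
    x and y after cropping."""

    original_shape: tuple
    original_spacing: tuple
    crop_lo: tuple
    crop_hi: tuple
    inplane_scale: float = 1.0

    def __post_init__(self):
        self.original_shape = tuple(int(s) for s in self.original_shape)
        self.original_spacing = tuple(float(s) for s in self.original_spacing)
        self.crop_lo = tuple(int(v) for v in self.crop_lo)
        self.crop_hi = tuple(int(v) for v in self.crop_hi)
        for lo, hi, n in zip(self.crop_lo, self.crop_hi, self.original_shape):
            if not (0 <= lo < hi <= n):
                raise ValueError("crop box must satisfy 0 <= lo < hi <= shape")
        if not 0 < self.inplane_scale <= 1:
            raise ValueError("inplane scale must lie in (0, 1]")

    @property
    def crop_shape(self):
        return tuple(hi - lo for lo, hi in zip(self.crop_lo, self.crop_hi))

    @property
    def processed_shape(self):
        """Grid shape after cropping and in-plane rescaling."""
        cx, cy, cz = self.crop_shape
        f = self.inplane_scale
        return (max(1, round(cx * f)), max(1, round(cy * f)), cz)

    def to_json(self) -> str:
        return json.dumps({
            "original_shape": list(self.original_shape),
            "original_spacing": list(self.original_spacing),
            "crop_lo": list(self.crop_lo),
            "crop_hi": list(self.crop_hi),
            "inplane_scale": self.inplane_scale,
        }, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "PreprocessRecord":
        d = json.loads(text)
        return cls(**d)
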