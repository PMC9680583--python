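"""Core in-memory containers for volumes, normalized slices and dose grids.

Conventions: CT volumes are in Hounsfield Units with air at -1024 HU; MRI
volumes are non-negative arbitrary units; voxel arrays are (z, y, x) with
spacing (dz, dy, dx) in mm.  Values outside a body mask are -1024 HU for CT
and 0 for MRI.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

AIR_HU = -1024.0
#: fixed CT display/normalisation window used to invert synthetic CT to HU
CT_BOUNDS = (-1024.0, 3071.0)


@dataclass
class HUVolume:
    """3D CT-like scalar grid in Hounsfield Units."""
    voxels: np.ndarray
    spacing: tuple = (1.0, 1.0, 1.0)
    body_mask: Optional[np.ndarray] = None

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 3:
            raise ValueError("HUVolume requires a 3D voxel grid")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing components must be positive")
        if np.any(self.voxels < AIR_HU):
            raise ValueError("HU values below -1024 are invalid")
        if self.body_mask is not None:
            self.body_mask = np.asarray(self.body_mask, dtype=bool)
            if self.body_mask.shape != self.voxels.shape:
                raise ValueError("body_mask shape mismatch")


@dataclass
class MRVolume:
    """3D MRI scalar grid in arbitrary non-negative units."""
    voxels: np.ndarray
    spacing: tuple = (1.0, 1.0, 1.0)
    body_mask: Optional[np.ndarray] = None

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 3:
            raise ValueError("MRVolume requires a 3D voxel grid")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing components must be positive")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("MRI voxels must be finite")


@dataclass
class NormalizedImage:
    """2D image scaled to [-1, 1] with the source (min, max) retained so the
    affine normalisation can be inverted exactly."""
    pixels: np.ndarray
    source_min: float
    source_max: float

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError("NormalizedImage requires a 2D grid")
        if not self.source_max > self.source_min:
            raise ValueError("source_max must exceed source_min")
        lo, hi = self.pixels.min(), self.pixels.max()
        if lo < -1.0 - 1e-9 or hi > 1.0 + 1e-9:
            raise ValueError("pixels must lie in [-1, 1]")


@dataclass
class DoseGrid:
    """3D radiation dose grid in Gy with a prescription dose for global
    gamma normalisation (prescription default 50 Gy)."""
    dose: np.ndarray
    spacing: tuple = (1.0, 1.0, 1.0)
    prescription: float = 50.0

    def __post_init__(self):
        self.dose = np.asarray(self.dose, dtype=np.float64)
        if self.dose.ndim != 3:
            raise ValueError("DoseGrid requires a 3D grid")
        if np.any(self.dose < 0):
            raise ValueError("dose must be non-negative")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing components must be positive")
        if self.prescription <= 0:
            raise ValueError("prescription dose must be positive")
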