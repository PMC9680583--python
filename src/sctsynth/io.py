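"""NIfTI volume I/O and the subject manifest.

Volumes are stored as 3D NIfTI images whose affine carries the voxel
spacing; in memory the package uses (z, y, x) arrays, on disk the
conventional (x, y, z) order.  The manifest is a plain-text table listing
one subject per row with its CT/MRI paths and train/test split tag.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import List, Optional, Union

import nibabel as nib
import numpy as np

from .containers import HUVolume, MRVolume

__all__ = ["read_volume", "write_volume", "read_mask", "write_mask",
           "ManifestRow", "Manifest"]


def _load_3d(path: str):
    img = nib.load(path)
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got {data.ndim}D")
    zooms = img.header.get_zooms()[:3]
    if any(z <= 0 for z in zooms):
        raise ValueError(f"{path}: missing or invalid voxel spacing")
    # disk (x, y, z) -> memory (z, y, x); spacing likewise reversed
    return np.asarray(data, dtype=np.float64).T, tuple(float(z) for z in zooms[::-1])


def read_volume(path: str, kind: Optional[str] = None,
                ) -> Union[HUVolume, MRVolume]:
    """Load a NIfTI volume as CT (``kind='ct'``) or MRI (``kind='mri'``).

    With ``kind=None`` the modality is inferred from the intensity range:
    negative values mean Hounsfield Units.
    """
    vox, spacing = _load_3d(path)
    if kind is None:
        kind = "ct" if vox.min() < 0 else "mri"
    if kind == "ct":
        return HUVolume(np.maximum(vox, -1024.0), spacing)
    if kind == "mri":
        return MRVolume(np.maximum(vox, 0.0), spacing)
    raise ValueError(f"unknown volume kind {kind!r}")


def write_volume(vol: Union[HUVolume, MRVolume], path: str) -> None:
    dz, dy, dx = vol.spacing
    affine = np.diag([dx, dy, dz, 1.0])
    img = nib.Nifti1Image(np.asarray(vol.voxels.T, dtype=np.float32), affine)
    img.header.set_zooms((dx, dy, dz))
    nib.save(img, path)


def read_mask(path: str) -> np.ndarray:
    vox, _ = _load_3d(path)
    return vox > 0.5


def write_mask(mask: np.ndarray, spacing, path: str) -> None:
    dz, dy, dx = spacing
    img = nib.Nifti1Image(np.asarray(mask.T, dtype=np.uint8),
                          np.diag([dx, dy, dz, 1.0]))
    nib.save(img, path)


@dataclass(frozen=True)
class ManifestRow:
    subject_id: str
    ct_path: str
    mri_path: str
    split: str

    def __post_init__(self):
        if self.split not in ("train", "test"):
            raise ValueError(f"split must be 'train' or 'test', got {self.split!r}")


@dataclass
class Manifest:
    rows: List[ManifestRow]

    HEADER = ("subject_id", "ct_path", "mri_path", "split")

    def subjects(self, split: Optional[str] = None) -> List[ManifestRow]:
        return [r for r in self.rows if split is None or r.split == split]

    def validate_paths(self) -> None:
        for r in self.rows:
            for p in (r.ct_path, r.mri_path):
                if not os.path.exists(p):
                    raise FileNotFoundError(f"manifest entry {r.subject_id}: "
                                            f"missing file {p}")

    def write(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("\t".join(self.HEADER) + "\n")
            for r in self.rows:
                fh.write(f"{r.subject_id}\t{r.ct_path}\t{r.mri_path}\t{r.split}\n")

    @classmethod
    def read(cls, path: str) -> "Manifest":
        rows = []
        with open(path) as fh:
            header = fh.readline().strip().split("\t")
            if tuple(header) != cls.HEADER:
                raise ValueError(f"{path}: unexpected manifest header {header}")
            for line in fh:
                if not line.strip():
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) != 4:
                    raise ValueError(f"{path}: malformed manifest row {parts}")
                rows.append(ManifestRow(*parts))
        return cls(rows)
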