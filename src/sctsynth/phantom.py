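"""Synthetic paired MRI/CT head phantoms and the preprocessing chain.

The phantom emulates head anatomy on a regular grid at 1 x 1 x 1 mm
spacing: an outer soft-tissue head ellipsoid, a bone skull shell, a brain
compartment, one to three CSF ventricle blobs and an optional tumor blob.
Per-subject shape jitter perturbs the ellipsoid axes so subjects differ in
geometry while sharing the same tissue intensity table.  CT and MRI are
generated from the same label field, so the pair is voxelwise aligned with
a known cross-modality intensity mapping — the property every downstream
training and evaluation test relies on.

The default tissue table reproduces the T1 contrast inversion at bone
(bone bright in CT, dark in T1 MRI).  ``monotone_tissue_table`` provides an
alternative table whose MRI-to-CT mapping is strictly monotone, used by the
parameter-recovery training tests where a learnable ground-truth mapping is
required.

Preprocessing mirrors the standard MRI-only planning chain: body masking by
thresholding + largest connected component + hole filling, histogram
matching of MRI intensities to a reference scan, [-1, 1] normalisation
(exactly invertible via the stored bounds), and axial slicing to a fixed
stored size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .containers import AIR_HU, CT_BOUNDS, DoseGrid, HUVolume, MRVolume, NormalizedImage

__all__ = [
    "TissueRow", "PhantomSpec", "default_tissue_table", "monotone_tissue_table",
    "generate_phantom_pair", "make_body_mask", "apply_masks", "histogram_match",
    "normalize_unit", "denormalize_unit", "slice_dataset", "surrogate_dose",
]

MIN_GRID = 16


@dataclass(frozen=True)
class TissueRow:
    name: str
    ct_mean: float
    ct_sd: float
    mri_mean: float
    mri_sd: float


def default_tissue_table() -> List[TissueRow]:
    """Head tissue intensities with T1-like contrast inversion at bone."""
    return [
        TissueRow("air", -1024.0, 0.0, 0.0, 0.0),
        TissueRow("soft_tissue", 40.0, 15.0, 300.0, 20.0),
        TissueRow("bone", 1000.0, 60.0, 100.0, 10.0),
        TissueRow("csf", 10.0, 10.0, 150.0, 15.0),
        TissueRow("tumor", 50.0, 15.0, 400.0, 25.0),
    ]


def monotone_tissue_table() -> List[TissueRow]:
    """Tissue table whose MRI -> CT intensity mapping is strictly monotone
    (air < CSF < soft tissue < tumor < bone in both modalities).  Not
    T1-realistic; intended for learnability tests where the ground-truth
    mapping must be representable by a monotone intensity transform."""
    return [
        TissueRow("air", -1024.0, 0.0, 0.0, 0.0),
        TissueRow("csf", 10.0, 5.0, 150.0, 8.0),
        TissueRow("soft_tissue", 40.0, 8.0, 300.0, 10.0),
        TissueRow("tumor", 55.0, 8.0, 380.0, 10.0),
        TissueRow("bone", 1000.0, 30.0, 600.0, 15.0),
    ]


@dataclass(frozen=True)
class PhantomSpec:
    n_subjects: int = 4
    grid_shape: Tuple[int, int, int] = (32, 64, 64)
    seed: int = 0
    shape_jitter: float = 0.08
    tissue_table: Tuple[TissueRow, ...] = ()
    #: default phantoms emulate the T1 bone/soft-tissue contrast inversion;
    #: learnability harnesses may disable the check to use a monotone table
    require_contrast_inversion: bool = True

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if any(s < MIN_GRID for s in self.grid_shape):
            raise ValueError(f"grid_shape components must be >= {MIN_GRID}")
        table = self.tissue_table or tuple(default_tissue_table())
        object.__setattr__(self, "tissue_table", tuple(table))
        names = {r.name for r in self.tissue_table}
        required = {"air", "bone", "soft_tissue", "csf"}
        if not required <= names:
            raise ValueError(f"tissue_table must contain {sorted(required)}")
        rows = {r.name: r for r in self.tissue_table}
        if rows["bone"].ct_mean <= rows["soft_tissue"].ct_mean:
            raise ValueError("CT bone mean must exceed CT soft-tissue mean")
        if self.require_contrast_inversion and \
                rows["bone"].mri_mean >= rows["soft_tissue"].mri_mean:
            raise ValueError("MRI bone mean must be below MRI soft-tissue mean "
                             "(contrast inversion)")

    def tissue(self, name: str) -> TissueRow:
        for row in self.tissue_table:
            if row.name == name:
                return row
        raise KeyError(name)


def _ellipsoid(shape, center, semi_axes) -> np.ndarray:
    """Boolean ellipsoid mask in normalised [-1, 1] coordinates per axis."""
    grids = np.meshgrid(*[np.linspace(-1.0, 1.0, n) for n in shape],
                        indexing="ij", sparse=True)
    r2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi_axes))
    return r2 <= 1.0


def _label_field(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    shape = spec.grid_shape
    jit = spec.shape_jitter
    head_axes = 0.85 * (1.0 + jit * rng.uniform(-1, 1, size=3))
    head_axes = np.clip(head_axes, 0.5, 0.98)
    labels = np.zeros(shape, dtype=np.int8)  # 0 air
    head = _ellipsoid(shape, (0, 0, 0), head_axes)
    skull_out = _ellipsoid(shape, (0, 0, 0), head_axes * 0.88)
    skull_in = _ellipsoid(shape, (0, 0, 0), head_axes * 0.74)
    labels[head] = 1                     # scalp / soft tissue
    labels[skull_out & ~skull_in] = 2    # bone shell
    labels[skull_in] = 1                 # brain
    shell_voxels = int(np.count_nonzero(labels == 2))
    if shell_voxels == 0:
        raise ValueError(
            f"grid {shape} too small to contain the skull shell; minimum "
            f"shape is ({MIN_GRID}, {MIN_GRID}, {MIN_GRID})")
    n_vent = int(rng.integers(1, 4))
    for _ in range(n_vent):
        c = rng.uniform(-0.15, 0.15, size=3)
        a = rng.uniform(0.06, 0.14, size=3)
        labels[_ellipsoid(shape, c, a) & skull_in] = 3   # CSF
    if rng.uniform() < 0.5 and any(r.name == "tumor" for r in spec.tissue_table):
        c = rng.uniform(-0.35, 0.35, size=3)
        a = rng.uniform(0.06, 0.12, size=3)
        labels[_ellipsoid(shape, c, a) & skull_in & (labels != 3)] = 4
    return labels


_LABEL_NAMES = {0: "air", 1: "soft_tissue", 2: "bone", 3: "csf", 4: "tumor"}


def generate_phantom_pair(spec: PhantomSpec, subject_index: int
                          ) -> Tuple[HUVolume, MRVolume]:
    """Voxelwise-aligned CT/MRI pair for one subject.

    Deterministic given ``(spec.seed, subject_index)``.  The returned
    volumes carry the anatomy-derived body mask and are already masked
    (CT -1024 HU and MRI 0 outside the body).
    """
    if not 0 <= subject_index < spec.n_subjects:
        raise ValueError(f"subject_index {subject_index} out of range "
                         f"[0, {spec.n_subjects})")
    rng = np.random.default_rng([spec.seed, subject_index])
    labels = _label_field(spec, rng)
    ct = np.full(spec.grid_shape, AIR_HU)
    mri = np.zeros(spec.grid_shape)
    for lab, name in _LABEL_NAMES.items():
        sel = labels == lab
        if not np.any(sel):
            continue
        try:
            row = spec.tissue(name)
        except KeyError:
            continue
        n = int(np.count_nonzero(sel))
        ct[sel] = row.ct_mean + row.ct_sd * rng.standard_normal(n)
        mri[sel] = row.mri_mean + row.mri_sd * rng.standard_normal(n)
    ct = np.maximum(ct, AIR_HU)
    mri = np.maximum(mri, 0.0)
    mask = labels > 0
    ct[~mask] = AIR_HU
    mri[~mask] = 0.0
    return (HUVolume(ct, (1.0, 1.0, 1.0), mask),
            MRVolume(mri, (1.0, 1.0, 1.0), mask))


def make_body_mask(ct: HUVolume, threshold_hu: float = -400.0) -> np.ndarray:
    """Body mask from CT: voxels above ``threshold_hu``, reduced to the
    largest 3D connected component, with internal holes filled slice-wise
    (so air cavities enclosed by anatomy stay inside the mask)."""
    if not np.all(np.isfinite(ct.voxels)):
        raise ValueError("CT volume contains non-finite values")
    fg = ct.voxels > threshold_hu
    if not np.any(fg):
        raise ValueError("empty mask: no voxel above threshold")
    comp, n = ndimage.label(fg)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(comp), comp, index=np.arange(1, n + 1))
        fg = comp == (1 + int(np.argmax(sizes)))
    filled = np.empty_like(fg)
    for z in range(fg.shape[0]):
        filled[z] = ndimage.binary_fill_holes(fg[z])
    return filled


def apply_masks(ct: HUVolume, mri: MRVolume, mask: np.ndarray
                ) -> Tuple[HUVolume, MRVolume]:
    """Set voxels outside ``mask`` to -1024 HU (CT) and 0 (MRI)."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != ct.voxels.shape or mask.shape != mri.voxels.shape:
        raise ValueError("mask/volume shape mismatch")
    ct_out = ct.voxels.copy()
    mri_out = mri.voxels.copy()
    ct_out[~mask] = AIR_HU
    mri_out[~mask] = 0.0
    return (HUVolume(ct_out, ct.spacing, mask), MRVolume(mri_out, mri.spacing, mask))


def histogram_match(mri: MRVolume, reference: MRVolume, n_levels: int = 256
                    ) -> MRVolume:
    """Monotone intensity remap of ``mri`` so its masked empirical CDF
    matches the reference CDF at ``n_levels`` quantile landmarks.

    The map is piecewise-linear interpolation between matched quantiles,
    hence rank-preserving.  Voxels outside the body mask stay 0.
    """
    def _inside(vol: MRVolume) -> np.ndarray:
        vals = vol.voxels[vol.body_mask] if vol.body_mask is not None \
            else vol.voxels.ravel()
        if vals.size == 0 or np.ptp(vals) == 0:
            raise ValueError("constant volume: histogram matching undefined")
        return vals

    src, ref = _inside(mri), _inside(reference)
    q = np.linspace(0.0, 1.0, max(int(n_levels), 2))
    src_q = np.quantile(src, q)
    ref_q = np.quantile(ref, q)
    mapped = np.interp(mri.voxels, src_q, ref_q)
    if mri.body_mask is not None:
        mapped[~mri.body_mask] = 0.0
    return MRVolume(np.maximum(mapped, 0.0), mri.spacing, mri.body_mask)


def normalize_unit(image: np.ndarray) -> NormalizedImage:
    """Affine rescale of a 2D image to [-1, 1] from its own (min, max)."""
    image = np.asarray(image, dtype=np.float64)
    lo, hi = float(image.min()), float(image.max())
    if not hi > lo:
        raise ValueError("constant image: normalisation scale undefined")
    pixels = 2.0 * (image - lo) / (hi - lo) - 1.0
    return NormalizedImage(pixels, lo, hi)


def denormalize_unit(norm: NormalizedImage) -> np.ndarray:
    """Exact affine inverse of :func:`normalize_unit` via the stored bounds."""
    lo, hi = norm.source_min, norm.source_max
    return 0.5 * (norm.pixels + 1.0) * (hi - lo) + lo


def _center_crop_pad(plane: np.ndarray, size: int, fill: float) -> np.ndarray:
    out = np.full((size, size), fill)
    h, w = plane.shape
    # source and destination windows for each axis
    sh, dh = max(0, (h - size) // 2), max(0, (size - h) // 2)
    sw, dw = max(0, (w - size) // 2), max(0, (size - w) // 2)
    ch, cw = min(h, size), min(w, size)
    out[dh:dh + ch, dw:dw + cw] = plane[sh:sh + ch, sw:sw + cw]
    return out


def slice_dataset(volume, plane: str = "axial", size: int = 240,
                  bounds: Optional[Tuple[float, float]] = None
                  ) -> List[NormalizedImage]:
    """Axial 2D slices of a volume, centre-cropped/padded to ``size`` and
    normalised to [-1, 1].  Slices whose body mask is empty are dropped.

    CT volumes use the fixed CT window by default so every slice shares one
    invertible HU scale; MRI volumes use the volume's own (min, max).  The
    padding fill is the background value (-1024 HU / 0) so padded regions
    map to the normalised background.
    """
    if plane != "axial":
        raise ValueError("only axial slicing is supported")
    is_ct = isinstance(volume, HUVolume)
    fill = AIR_HU if is_ct else 0.0
    if bounds is None:
        if is_ct:
            bounds = CT_BOUNDS
        else:
            lo, hi = float(volume.voxels.min()), float(volume.voxels.max())
            if not hi > lo:
                raise ValueError("constant volume cannot be normalised")
            bounds = (lo, hi)
    lo, hi = bounds
    slices = []
    for z in range(volume.voxels.shape[0]):
        if volume.body_mask is not None and not volume.body_mask[z].any():
            continue
        plane2d = _center_crop_pad(volume.voxels[z], size, fill)
        pixels = np.clip(2.0 * (plane2d - lo) / (hi - lo) - 1.0, -1.0, 1.0)
        slices.append(NormalizedImage(pixels, lo, hi))
    return slices


def surrogate_dose(ct: HUVolume, prescription: float = 50.0,
                   angles_deg: Sequence[float] = (30, 90, 140, 180, 220, 275, 330),
                   sigma_mm: float = 8.0, sigma_z_mm: float = 12.0,
                   mu_per_mm: float = 0.004, normalize: bool = True) -> DoseGrid:
    """Synthetic analytic dose surrogate: a sum of attenuated Gaussian
    photon beams through the phantom, one per gantry angle in the axial
    plane, normalised to the prescription at the grid centre.

    This is a stand-in for a treatment-planning-system dose: it responds to
    HU differences through the water-equivalent path length (relative
    density (HU + 1024) / 1024) so dose grids computed on CT and synthetic
    CT differ in a physically sensible way, which is all the gamma-analysis
    code requires of it.

    With ``normalize=True`` the grid is scaled so the centre voxel receives
    the prescription.  When comparing a CT-based and an sCT-based dose, the
    sCT dose must be computed with ``normalize=False`` and scaled by the
    CT dose's factor (same delivery, different attenuation), otherwise the
    renormalisation would mask the HU-driven difference.
    """
    dz, dy, dx = ct.spacing
    density = np.clip((ct.voxels - AIR_HU) / 1024.0, 0.0, 3.0)
    nz, ny, nx = density.shape
    xprof = np.exp(-0.5 * ((np.arange(nx) - (nx - 1) / 2) * dx / sigma_mm) ** 2)
    zprof = np.exp(-0.5 * ((np.arange(nz) - (nz - 1) / 2) * dz / sigma_z_mm) ** 2)
    total = np.zeros_like(density)
    for ang in angles_deg:
        rot = ndimage.rotate(density, -float(ang), axes=(1, 2), order=1,
                             reshape=False, mode="constant", cval=0.0)
        wepl = np.cumsum(rot, axis=1) * dy            # mm of water upstream
        fluence = np.exp(-mu_per_mm * wepl)
        beam = fluence * rot * xprof[None, None, :] * zprof[:, None, None]
        total += ndimage.rotate(beam, float(ang), axes=(1, 2), order=1,
                                reshape=False, mode="constant", cval=0.0)
    if normalize:
        center = total[nz // 2, ny // 2, nx // 2]
        total = total * (prescription / center if center > 0 else 0.0)
    return DoseGrid(np.maximum(total, 0.0), ct.spacing, prescription)
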