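"""Image-quality metrics, 3D gamma analysis and the paired t-test.

Image metrics compare a synthetic CT with the real CT inside a region of
interest (by convention the body mask):

* MAE  = (1/N) sum |CT_i - sCT_i|                                (HU)
* PSNR = 10 log10( Q^2 / MSE )                                   (dB)
* SSIM = (2 mu_a mu_b + C1)(2 cov + C2)
         / ((mu_a^2 + mu_b^2 + C1)(sd_a^2 + sd_b^2 + C2))

with Q the maximum HU value over the ROI of the two images, C1 = (0.01 Q)^2
and C2 = (0.03 Q)^2.  SSIM here is the single global statistic (one mean,
variance and covariance per image), not a windowed mean.

Gamma analysis is the standard global 3D index: for each reference voxel r,

    gamma(r) = min_e sqrt( |r - e|^2 / dta^2
                           + (D_eval(e) - D_ref(r))^2 / (dd * D_rx)^2 )

minimised over evaluated voxels e within a search radius (default 3 x dta),
with the dose difference normalised to the prescription dose D_rx
("global" normalisation).  A voxel passes when gamma <= 1; passing rates
are reported over voxels whose reference dose exceeds a threshold fraction
of the prescription.  The index is directional (reference vs evaluated) —
no symmetry is assumed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Tuple

import numpy as np
from scipy import stats

from .containers import DoseGrid, HUVolume

__all__ = [
    "MetricReport", "GammaResult", "mae", "psnr", "ssim", "metric_report",
    "gamma_index_map", "gamma_passing_rate", "gamma_grid_report",
    "brute_force_gamma_oracle", "paired_ttest",
    "GAMMA_CRITERIA", "DOSE_THRESHOLDS",
]

#: the (dose-difference %, DTA mm) criteria grid of the evaluation protocol
GAMMA_CRITERIA: Tuple[Tuple[float, float], ...] = ((2.0, 2.0), (3.0, 3.0))
#: dose thresholds as % of prescription
DOSE_THRESHOLDS: Tuple[float, ...] = (10.0, 30.0, 50.0, 70.0, 90.0)


@dataclass
class MetricReport:
    mae_hu: float
    psnr_db: float
    ssim: float
    n_voxels: int
    q_hu: float

    def as_dict(self) -> dict:
        return {"mae_hu": self.mae_hu, "psnr_db": self.psnr_db,
                "ssim": self.ssim, "n_voxels": self.n_voxels, "q_hu": self.q_hu}


@dataclass
class GammaResult:
    dd_percent: float
    dta_mm: float
    threshold_percent: float
    passing_rate: float
    n_evaluated: int

    def as_dict(self) -> dict:
        return {"dd_percent": self.dd_percent, "dta_mm": self.dta_mm,
                "threshold_percent": self.threshold_percent,
                "passing_rate": self.passing_rate,
                "n_evaluated": self.n_evaluated}


def _roi_values(ct: HUVolume, sct: HUVolume, roi) -> Tuple[np.ndarray, np.ndarray]:
    if ct.voxels.shape != sct.voxels.shape:
        raise ValueError("CT and sCT shapes differ")
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != ct.voxels.shape:
        raise ValueError("ROI shape mismatch")
    if not roi.any():
        raise ValueError("empty ROI")
    return ct.voxels[roi], sct.voxels[roi]


def mae(ct: HUVolume, sct: HUVolume, roi) -> float:
    """Mean absolute HU error over the ROI."""
    a, b = _roi_values(ct, sct, roi)
    return float(np.mean(np.abs(a - b)))


def _q_value(a: np.ndarray, b: np.ndarray) -> float:
    return float(max(a.max(), b.max()))


def psnr(ct: HUVolume, sct: HUVolume, roi) -> float:
    """Peak signal-to-noise ratio in dB; +inf when the volumes coincide."""
    a, b = _roi_values(ct, sct, roi)
    mse = float(np.mean((a - b) ** 2))
    if mse == 0.0:
        return float("inf")
    q = _q_value(a, b)
    return float(10.0 * np.log10(q * q / mse))


def ssim(ct: HUVolume, sct: HUVolume, roi) -> float:
    """Global structural similarity over the ROI (single-statistic form)."""
    a, b = _roi_values(ct, sct, roi)
    q = _q_value(a, b)
    c1, c2 = (0.01 * q) ** 2, (0.03 * q) ** 2
    mu_a, mu_b = a.mean(), b.mean()
    var_a, var_b = a.var(), b.var()
    cov = np.mean((a - mu_a) * (b - mu_b))
    num = (2 * mu_a * mu_b + c1) * (2 * cov + c2)
    den = (mu_a ** 2 + mu_b ** 2 + c1) * (var_a + var_b + c2)
    return float(num / den)


def metric_report(ct: HUVolume, sct: HUVolume, roi) -> MetricReport:
    a, b = _roi_values(ct, sct, roi)
    return MetricReport(mae_hu=mae(ct, sct, roi), psnr_db=psnr(ct, sct, roi),
                        ssim=ssim(ct, sct, roi), n_voxels=int(a.size),
                        q_hu=_q_value(a, b))


def _check_grids(ref: DoseGrid, ev: DoseGrid) -> None:
    if ref.dose.shape != ev.dose.shape:
        raise ValueError("dose grid shapes differ")
    if not np.allclose(ref.spacing, ev.spacing):
        raise ValueError("dose grid spacings differ")


def _neighbour_offsets(spacing, radius_mm: float):
    """Voxel offsets within radius, sorted by physical distance (0 first)."""
    dz, dy, dx = spacing
    nz = int(radius_mm // dz)
    ny = int(radius_mm // dy)
    nx = int(radius_mm // dx)
    offs, dists = [], []
    for oz in range(-nz, nz + 1):
        for oy in range(-ny, ny + 1):
            for ox in range(-nx, nx + 1):
                d = np.sqrt((oz * dz) ** 2 + (oy * dy) ** 2 + (ox * dx) ** 2)
                if d <= radius_mm:
                    offs.append((oz, oy, ox))
                    dists.append(d)
    order = np.argsort(dists, kind="stable")
    return [offs[i] for i in order], np.asarray(dists)[order]


def _shift_window(shape, off):
    """Index slices so dst[dst_sl] aligns with src[src_sl] shifted by off."""
    dst_sl, src_sl = [], []
    for n, o in zip(shape, off):
        if o >= 0:
            dst_sl.append(slice(0, n - o))
            src_sl.append(slice(o, n))
        else:
            dst_sl.append(slice(-o, n))
            src_sl.append(slice(0, n + o))
    return tuple(dst_sl), tuple(src_sl)


def gamma_index_map(ref: DoseGrid, ev: DoseGrid, dd_percent: float,
                    dta_mm: float, search_radius_mm: float = None) -> np.ndarray:
    """Global 3D gamma index per reference voxel.

    The evaluated-dose search visits voxel centres within the search radius
    (default 3 x DTA) in order of increasing distance and stops once the
    distance term alone can no longer improve any voxel's running minimum.
    """
    _check_grids(ref, ev)
    if dd_percent <= 0 or dta_mm <= 0:
        raise ValueError("dd and dta criteria must be positive")
    if search_radius_mm is None:
        search_radius_mm = 3.0 * dta_mm
    dose_tol = dd_percent / 100.0 * ref.prescription
    offsets, dists = _neighbour_offsets(ref.spacing, search_radius_mm)
    g2 = np.full(ref.dose.shape, np.inf)
    for off, d in zip(offsets, dists):
        worst = np.sqrt(g2.max()) if np.isfinite(g2.max()) else np.inf
        if d / dta_mm >= worst:
            break
        dst_sl, src_sl = _shift_window(ref.dose.shape, off)
        diff = (ev.dose[src_sl] - ref.dose[dst_sl]) / dose_tol
        cand = (d / dta_mm) ** 2 + diff * diff
        np.minimum(g2[dst_sl], cand, out=g2[dst_sl])
    return np.sqrt(g2)


def brute_force_gamma_oracle(ref: DoseGrid, ev: DoseGrid, dd_percent: float,
                             dta_mm: float) -> np.ndarray:
    """Exhaustive gamma over ALL evaluated voxels (no search-radius cutoff).

    Test oracle only; refuses grids larger than 32^3.
    """
    _check_grids(ref, ev)
    if ref.dose.size > 32 ** 3:
        raise ValueError("brute-force gamma oracle limited to grids <= 32^3")
    dz, dy, dx = ref.spacing
    nz, ny, nx = ref.dose.shape
    zz, yy, xx = np.meshgrid(np.arange(nz) * dz, np.arange(ny) * dy,
                             np.arange(nx) * dx, indexing="ij")
    pos = np.stack([zz.ravel(), yy.ravel(), xx.ravel()], axis=1)
    dref = ref.dose.ravel()
    dev = ev.dose.ravel()
    dose_tol = dd_percent / 100.0 * ref.prescription
    out = np.empty(dref.size)
    chunk = 256
    for start in range(0, dref.size, chunk):
        sl = slice(start, min(start + chunk, dref.size))
        dist2 = ((pos[sl, None, :] - pos[None, :, :]) ** 2).sum(axis=2)
        dosed2 = ((dev[None, :] - dref[sl, None]) / dose_tol) ** 2
        out[sl] = np.sqrt((dist2 / dta_mm ** 2 + dosed2).min(axis=1))
    return out.reshape(ref.dose.shape)


def gamma_passing_rate(ref: DoseGrid, ev: DoseGrid, dd_percent: float,
                       dta_mm: float, threshold_percent: float,
                       search_radius_mm: float = None) -> GammaResult:
    """Percent of above-threshold reference voxels with gamma <= 1."""
    gmap = gamma_index_map(ref, ev, dd_percent, dta_mm, search_radius_mm)
    sel = ref.dose >= threshold_percent / 100.0 * ref.prescription
    n = int(np.count_nonzero(sel))
    if n == 0:
        raise ValueError(f"no reference voxel above {threshold_percent}% "
                         "of the prescription dose")
    rate = 100.0 * float(np.count_nonzero(gmap[sel] <= 1.0)) / n
    return GammaResult(dd_percent, dta_mm, threshold_percent, rate, n)


def gamma_grid_report(ref: DoseGrid, ev: DoseGrid) -> List[GammaResult]:
    """The full criteria x threshold grid (2%/2mm and 3%/3mm by 10..90%)."""
    out = []
    for dd, dta in GAMMA_CRITERIA:
        gmap = gamma_index_map(ref, ev, dd, dta)
        for thr in DOSE_THRESHOLDS:
            sel = ref.dose >= thr / 100.0 * ref.prescription
            n = int(np.count_nonzero(sel))
            if n == 0:
                raise ValueError(f"no reference voxel above {thr}% threshold")
            rate = 100.0 * float(np.count_nonzero(gmap[sel] <= 1.0)) / n
            out.append(GammaResult(dd, dta, thr, rate, n))
    return out


def paired_ttest(values_a, values_b) -> Tuple[float, float]:
    """Classical two-tailed paired t-test on per-subject metric values."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be equal-length 1D sequences")
    if a.size < 2:
        raise ValueError("need at least two paired observations")
    d = a - b
    if np.std(d, ddof=1) == 0:
        raise ValueError("degenerate input: differences have zero variance")
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)
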