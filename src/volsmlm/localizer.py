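"""Spot detection, anisotropic Gaussian fitting and astigmatic z assignment.

Detection uses an à-trous (undecimated) B3-spline wavelet decomposition;
candidate spots are connected components of the second wavelet plane above a
robust noise threshold.  Each candidate ROI is fitted with an elliptical 2D
Gaussian; the PSF anisotropy (σx, σy) is converted to an axial position via
a calibration measured on a bead z-stack.  Localizations are then filtered
on goodness of fit (χ² ∈ [0.6, 1], a coefficient-of-determination surrogate)
and axial range (z ∈ [−0.5, 0.5] µm).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, optimize
from scipy.interpolate import CubicSpline

from .sim_core import FrameStack

__all__ = [
    "AstigCalibration",
    "detect_spots",
    "fit_gaussian",
    "GaussianFit",
    "calibrate_astigmatism",
    "assign_z",
    "filter_localizations",
    "localize_stack",
    "LOC_COLUMNS",
]

#: Canonical in-memory localization table columns.
LOC_COLUMNS = [
    "loc_id",
    "frame",
    "x_nm",
    "y_nm",
    "z_um",
    "sigma_x_nm",
    "sigma_y_nm",
    "intensity_adu",
    "chi2",
    "plane_index",
]

_B3 = np.array([1.0, 4.0, 6.0, 4.0, 1.0]) / 16.0


def _atrous_smooth(img: np.ndarray, level: int) -> np.ndarray:
    """Separable B3-spline smoothing with 2**level - 1 holes."""
    kernel = np.zeros((len(_B3) - 1) * 2**level + 1)
    kernel[:: 2**level] = _B3
    out = ndimage.convolve1d(img, kernel, axis=0, mode="reflect")
    return ndimage.convolve1d(out, kernel, axis=1, mode="reflect")


def wavelet_planes(img: np.ndarray, levels: int = 3) -> list[np.ndarray]:
    """À-trous B3-spline wavelet planes W1..W<levels> of an image."""
    planes = []
    current = np.asarray(img, dtype=float)
    for level in range(levels):
        smooth = _atrous_smooth(current, level)
        planes.append(current - smooth)
        current = smooth
    return planes


def detect_spots(
    frame: np.ndarray,
    threshold_factor: float = 1.5,
    *,
    roi_px: int = 15,
    min_area_px: int = 4,
) -> list[tuple[int, int]]:
    """Detect candidate spots in a baseline-subtracted frame.

    Candidates are connected components of the second wavelet plane above
    ``threshold_factor`` times a MAD-based noise estimate of that plane.
    Returns ``(cy, cx)`` center pixels, one per component (the component's
    intensity peak).
    """
    w2 = wavelet_planes(frame, levels=2)[1]
    med = np.median(w2)
    sigma = 1.4826 * np.median(np.abs(w2 - med))
    thr = threshold_factor * sigma
    mask = w2 > max(thr, 1e-12)
    labels, n = ndimage.label(mask)
    centers: list[tuple[int, int]] = []
    if n == 0:
        return centers
    for sl in ndimage.find_objects(labels):
        component = labels[sl]
        lab = component.max()
        if np.count_nonzero(component == lab) < min_area_px:
            continue
        local = np.where(component == lab, w2[sl], -np.inf)
        cy, cx = np.unravel_index(np.argmax(local), local.shape)
        centers.append((sl[0].start + cy, sl[1].start + cx))
    return centers


@dataclass
class GaussianFit:
    """Result of an elliptical Gaussian fit on one ROI (pixel units -> nm)."""

    x_nm: float
    y_nm: float
    sigma_x_nm: float
    sigma_y_nm: float
    intensity_adu: float
    offset_adu: float
    chi2: float
    converged: bool


def _gauss_model(params, xg, yg):
    amp, x0, y0, sx, sy, off = params
    return amp * np.exp(
        -((xg - x0) ** 2) / (2 * sx**2) - ((yg - y0) ** 2) / (2 * sy**2)
    ) + off


def fit_gaussian(
    roi: np.ndarray,
    pixel_size_nm: float,
    origin_px: tuple[int, int] = (0, 0),
) -> GaussianFit:
    """Least-squares anisotropic 2D Gaussian fit of a ROI.

    ``origin_px`` is the (row, col) position of ``roi[0, 0]`` in the full
    frame, so fitted coordinates are returned in frame nm.  The goodness of
    fit is reported as a coefficient of determination
    ``chi2 = 1 − SS_res / SS_tot`` clamped to [0, 1] (best fits near 1).
    """
    roi = np.asarray(roi, dtype=float)
    if roi.shape[0] < 9 or roi.shape[1] < 9:
        raise ValueError("ROI must be at least 9x9 pixels")
    ny, nx = roi.shape
    yg, xg = np.mgrid[0:ny, 0:nx]
    off0 = float(np.percentile(roi, 20))
    amp0 = max(float(roi.max()) - off0, 1e-6)
    w = np.clip(roi - off0, 0, None)
    tot = w.sum()
    if tot > 0:
        x0 = float((w * xg).sum() / tot)
        y0 = float((w * yg).sum() / tot)
    else:
        x0, y0 = nx / 2, ny / 2
    p0 = [amp0, x0, y0, 1.5, 1.5, off0]
    lo = [0.0, -2.0, -2.0, 0.3, 0.3, -np.inf]
    hi = [np.inf, nx + 1.0, ny + 1.0, nx, ny, np.inf]

    def resid(p):
        return (_gauss_model(p, xg, yg) - roi).ravel()

    try:
        sol = optimize.least_squares(resid, p0, bounds=(lo, hi), max_nfev=400)
        converged = sol.status > 0
    except Exception:
        return GaussianFit(0, 0, 1, 1, 0, 0, 0.0, False)
    amp, x0, y0, sx, sy, off = sol.x
    ss_res = float(np.sum(sol.fun**2))
    ss_tot = float(np.sum((roi - roi.mean()) ** 2))
    chi2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    chi2 = float(np.clip(chi2, 0.0, 1.0))
    r0, c0 = origin_px
    return GaussianFit(
        x_nm=(c0 + x0) * pixel_size_nm,
        y_nm=(r0 + y0) * pixel_size_nm,
        sigma_x_nm=abs(sx) * pixel_size_nm,
        sigma_y_nm=abs(sy) * pixel_size_nm,
        intensity_adu=float(2 * np.pi * amp * abs(sx) * abs(sy)),
        offset_adu=float(off),
        chi2=chi2,
        converged=converged,
    )


@dataclass
class AstigCalibration:
    """σx(z), σy(z) calibration mapping PSF anisotropy to axial position.

    ``z_um`` is centered such that σx(0) = σy(0); the usable range is where
    σx − σy is strictly monotone.  ``symmetry_score`` is the normalized L2
    distance between σx(z) and σy(−z) (0 for a perfectly symmetric pair).
    """

    z_um: np.ndarray
    sigma_x_nm: np.ndarray
    sigma_y_nm: np.ndarray
    symmetry_score: float

    def __post_init__(self) -> None:
        self._sx = CubicSpline(self.z_um, self.sigma_x_nm)
        self._sy = CubicSpline(self.z_um, self.sigma_y_nm)

    def sigmas_at(self, z_um: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        return self._sx(z_um), self._sy(z_um)

    def lookup_grid(self, z_max_um: float = 0.5, step_um: float = 0.001):
        z = np.arange(-z_max_um, z_max_um + step_um / 2, step_um)
        z = np.clip(z, self.z_um[0], self.z_um[-1])
        return z, self._sx(z), self._sy(z)


def calibrate_astigmatism(
    bead_zstack: FrameStack,
    z_step_um: float,
    pixel_size_nm: float,
    *,
    z_usable_um: float = 0.4,
) -> AstigCalibration:
    """Build an astigmatism calibration from a bead z-stack.

    Each plane of the stack (one frame per z position, covering at least
    ±0.5 µm around focus) is fitted with an anisotropic Gaussian on the
    brightest spot; z is re-centered on the crossing σx(z*) = σy(z*), and
    σx − σy is required to be strictly monotone on ±``z_usable_um``.
    """
    n = bead_zstack.n_frames
    span = (n - 1) * z_step_um
    if span < 1.0:
        raise ValueError("bead z-stack must span at least ±0.5 µm")
    if z_step_um > 0.05:
        raise ValueError("z step must be <= 50 nm")
    zs, sxs, sys_ = [], [], []
    for i in range(n):
        frame = bead_zstack.frames[i].astype(float)
        frame = frame - np.median(frame)
        cy, cx = np.unravel_index(np.argmax(ndimage.gaussian_filter(frame, 1)), frame.shape)
        half = 7
        y0 = int(np.clip(cy - half, 0, frame.shape[0] - (2 * half + 1)))
        x0 = int(np.clip(cx - half, 0, frame.shape[1] - (2 * half + 1)))
        roi = frame[y0 : y0 + 2 * half + 1, x0 : x0 + 2 * half + 1]
        fit = fit_gaussian(roi, pixel_size_nm, origin_px=(y0, x0))
        if not fit.converged:
            continue
        zs.append(i * z_step_um)
        sxs.append(fit.sigma_x_nm)
        sys_.append(fit.sigma_y_nm)
    z = np.array(zs)
    sx = np.array(sxs)
    sy = np.array(sys_)
    diff = sx - sy
    # focal position: zero crossing of sigma_x - sigma_y closest to mid-stack
    sign_change = np.where(np.diff(np.sign(diff)) != 0)[0]
    if len(sign_change) == 0:
        raise ValueError("calibration rejected: sigma_x - sigma_y never crosses zero")
    mid = z[len(z) // 2]
    k = sign_change[np.argmin(np.abs(z[sign_change] - mid))]
    # linear interpolation of the crossing
    z_star = z[k] - diff[k] * (z[k + 1] - z[k]) / (diff[k + 1] - diff[k])
    z_rel = z - z_star

    usable = np.abs(z_rel) <= z_usable_um + 1e-9
    d_usable = diff[usable]
    steps = np.diff(d_usable)
    if not (np.all(steps > 0) or np.all(steps < 0)):
        raise ValueError("calibration rejected: sigma_x - sigma_y non-monotone")

    sx_spline = CubicSpline(z_rel, sx)
    sy_spline = CubicSpline(z_rel, sy)
    zz = np.linspace(max(z_rel[0], -z_usable_um), min(z_rel[-1], z_usable_um), 101)
    a = sx_spline(zz)
    b = sy_spline(-zz)
    symmetry = float(np.linalg.norm(a - b) / np.linalg.norm(0.5 * (a + b)))
    return AstigCalibration(
        z_um=z_rel, sigma_x_nm=sx, sigma_y_nm=sy, symmetry_score=symmetry
    )


def assign_z(
    sigma_x_nm: np.ndarray | float,
    sigma_y_nm: np.ndarray | float,
    cal: AstigCalibration,
    *,
    z_max_um: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Axial position by least-squares lookup in (σx, σy) space.

    For each localization, z minimizes ``(σx − σx_cal(z))² + (σy − σy_cal(z))²``
    on a 1 nm grid restricted to |z| ≤ ``z_max_um``.  Returns ``(z_um,
    out_of_range)``; the flag marks minima on the grid boundary.
    """
    zgrid, sx_g, sy_g = cal.lookup_grid(z_max_um=z_max_um, step_um=0.001)
    sx = np.atleast_1d(np.asarray(sigma_x_nm, dtype=float))
    sy = np.atleast_1d(np.asarray(sigma_y_nm, dtype=float))
    d2 = (sx[:, None] - sx_g[None, :]) ** 2 + (sy[:, None] - sy_g[None, :]) ** 2
    idx = np.argmin(d2, axis=1)
    z = zgrid[idx]
    out = (idx == 0) | (idx == len(zgrid) - 1)
    if np.isscalar(sigma_x_nm):
        return float(z[0]), bool(out[0])
    return z, out


def filter_localizations(
    locs: pd.DataFrame,
    chi2_min: float = 0.6,
    chi2_max: float = 1.0,
    z_min_um: float = -0.5,
    z_max_um: float = 0.5,
) -> pd.DataFrame:
    """Quality filter: keep χ² ∈ [0.6, 1] and z ∈ [−0.5, 0.5] µm (inclusive)."""
    keep = (
        (locs["chi2"] >= chi2_min)
        & (locs["chi2"] <= chi2_max)
        & (locs["z_um"] >= z_min_um)
        & (locs["z_um"] <= z_max_um)
    )
    return locs.loc[keep].reset_index(drop=True)


def localize_stack(
    stack: FrameStack,
    cal: AstigCalibration | None,
    pixel_size_nm: float,
    baseline_adu: float = 100.0,
    threshold_factor: float = 1.5,
    *,
    roi_px: int = 15,
    apply_filters: bool = False,
) -> pd.DataFrame:
    """Detect + fit + (optionally) z-assign every frame of a stack.

    Returns a localization table with :data:`LOC_COLUMNS`.  With ``cal``
    None, z is set to NaN (pure 2D localization).
    """
    rows = []
    half = roi_px // 2
    loc_id = 0
    for t in range(stack.n_frames):
        frame = stack.frames[t].astype(float) - baseline_adu
        for cy, cx in detect_spots(frame, threshold_factor, roi_px=roi_px):
            y0 = int(np.clip(cy - half, 0, frame.shape[0] - roi_px))
            x0 = int(np.clip(cx - half, 0, frame.shape[1] - roi_px))
            roi = frame[y0 : y0 + roi_px, x0 : x0 + roi_px]
            fit = fit_gaussian(roi, pixel_size_nm, origin_px=(y0, x0))
            if not fit.converged:
                continue
            rows.append(
                (
                    loc_id,
                    t,
                    fit.x_nm,
                    fit.y_nm,
                    np.nan,
                    fit.sigma_x_nm,
                    fit.sigma_y_nm,
                    fit.intensity_adu,
                    fit.chi2,
                    stack.plane_index,
                )
            )
            loc_id += 1
    locs = pd.DataFrame(rows, columns=LOC_COLUMNS)
    if cal is not None and len(locs):
        z, out = assign_z(locs["sigma_x_nm"].to_numpy(), locs["sigma_y_nm"].to_numpy(), cal)
        locs["z_um"] = z
        locs["z_out_of_range"] = out
    if apply_filters and len(locs):
        locs = filter_localizations(locs)
    return locs
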