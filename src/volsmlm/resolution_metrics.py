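"""Spatial resolution estimation: Fourier ring correlation and bead FWHM.

FRC: the localization table is split by localization-id parity into two
statistically independent halves, both are rendered with identical settings,
and for each lateral plane of the stack the ring-wise spectral correlation
between the two half-images is computed.  The resolution of a plane is the
inverse of the first frequency where the (smoothed) FRC curve drops below
the fixed 1/7 threshold; planes are aggregated as mean ± s.e.m.

Bead FWHM: localization clusters of individual photostable fiducials are
fitted with a 3D ellipsoid (principal axes of the point cloud); FWHM along
each axis is 2.35 × the standard deviation of the projections.  The two
short axes give the lateral resolution, the long axis the axial one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .volume_builder import RenderConfig, render_volume

__all__ = ["FrcResult", "BeadResolution", "frc_curve", "frc_resolution", "bead_fwhm_resolution"]

GAUSSIAN_FWHM_FACTOR = 2.35  # FWHM of a Gaussian in units of sigma


@dataclass
class FrcResult:
    """Per-plane FRC resolutions (nm) and their aggregate."""

    resolutions_nm: list[float]
    mean_nm: float
    sem_nm: float
    curves: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)
    unresolved_planes: list[int] = field(default_factory=list)


@dataclass
class BeadResolution:
    """Per-bead FWHM estimates from ellipsoid projections."""

    lateral_fwhm_nm: np.ndarray
    axial_fwhm_nm: np.ndarray
    axes: list[np.ndarray]
    n_beads: int
    mean_lateral_nm: float = 0.0
    sem_lateral_nm: float = 0.0
    mean_axial_nm: float = 0.0
    sem_axial_nm: float = 0.0
    tilted_beads: list[int] = field(default_factory=list)


def frc_curve(img1: np.ndarray, img2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Ring-wise Fourier correlation of two images (rings of 1 bin width).

    Returns (spatial frequency in cycles/pixel, FRC value per ring).
    """
    if img1.shape != img2.shape:
        raise ValueError("images must have identical shape")
    f1 = np.fft.fftshift(np.fft.fft2(img1))
    f2 = np.fft.fftshift(np.fft.fft2(img2))
    ny, nx = img1.shape
    fy = np.fft.fftshift(np.fft.fftfreq(ny))
    fx = np.fft.fftshift(np.fft.fftfreq(nx))
    fr = np.hypot(*np.meshgrid(fy, fx, indexing="ij"))
    n_rings = min(ny, nx) // 2
    ring = np.clip((fr * min(ny, nx)).astype(int), 0, n_rings)
    num = np.bincount(ring.ravel(), weights=np.real(f1 * np.conj(f2)).ravel(), minlength=n_rings + 1)
    d1 = np.bincount(ring.ravel(), weights=(np.abs(f1) ** 2).ravel(), minlength=n_rings + 1)
    d2 = np.bincount(ring.ravel(), weights=(np.abs(f2) ** 2).ravel(), minlength=n_rings + 1)
    denom = np.sqrt(d1 * d2)
    with np.errstate(invalid="ignore", divide="ignore"):
        frc = np.where(denom > 0, num / denom, 0.0)
    freq = np.arange(n_rings + 1) / min(ny, nx)
    return freq[1:n_rings], frc[1:n_rings]


def _smooth(values: np.ndarray, width: int = 3) -> np.ndarray:
    kernel = np.ones(width) / width
    return np.convolve(values, kernel, mode="same")


def _crossing_resolution(
    freq: np.ndarray, frc: np.ndarray, criterion: float, pixel_nm: float
) -> float | None:
    """Resolution (nm) from the first downward crossing of the criterion."""
    sm = _smooth(frc)
    if sm[0] < criterion:
        return None
    below = np.where(sm < criterion)[0]
    if len(below) == 0:
        return 2.0 * pixel_nm  # never drops below: Nyquist floor
    k = below[0]
    # linear interpolation of the crossing frequency
    f0, f1 = freq[k - 1], freq[k]
    v0, v1 = sm[k - 1], sm[k]
    fc = f0 + (v0 - criterion) * (f1 - f0) / (v0 - v1)
    return max(float(1.0 / fc * pixel_nm), 2.0 * pixel_nm)


def frc_resolution(
    volume: pd.DataFrame,
    cfg: RenderConfig,
    criterion: float = 1.0 / 7.0,
    *,
    min_locs_per_plane: int = 1000,
) -> FrcResult:
    """FRC resolution of a reconstructed volume, per rendered plane.

    The volume is split by ``loc_id`` parity, both halves are rendered with
    identical geometry, and each z-plane holding at least
    ``min_locs_per_plane`` localizations (per half-volume criterion applied
    to the full table) is analyzed.  Planes whose FRC never rises above the
    criterion are reported unresolved and excluded from the aggregate.
    """
    even = volume[volume["loc_id"] % 2 == 0]
    odd = volume[volume["loc_id"] % 2 == 1]
    if len(even) == 0 or len(odd) == 0:
        raise ValueError("volume too small for an even/odd split")
    # identical rendering grid for both halves, covering the union extent
    pad = 3 * cfg.blur_lateral_nm
    origin = (
        float(volume["x_nm"].min() - pad),
        float(volume["y_nm"].min() - pad),
        float(volume["z_nm"].min() - 3 * cfg.blur_axial_nm),
    )
    shape = (
        int(np.round((volume["z_nm"].max() - origin[2]) / cfg.plane_spacing_nm)) + 4,
        int(np.round((volume["y_nm"].max() - origin[1]) / cfg.sr_pixel_nm)) + 4,
        int(np.round((volume["x_nm"].max() - origin[0]) / cfg.sr_pixel_nm)) + 4,
    )
    s_even, _ = render_volume(even, cfg, origin_nm=origin, shape=shape)
    s_odd, _ = render_volume(odd, cfg, origin_nm=origin, shape=shape)

    z_bins = np.round((volume["z_nm"] - origin[2]) / cfg.plane_spacing_nm).astype(int)
    counts = z_bins.value_counts()

    resolutions, curves, unresolved = [], [], []
    for iz in range(shape[0]):
        if counts.get(iz, 0) < min_locs_per_plane:
            continue
        freq, frc = frc_curve(s_even[iz], s_odd[iz])
        curves.append((freq, frc))
        res = _crossing_resolution(freq, frc, criterion, cfg.sr_pixel_nm)
        if res is None:
            unresolved.append(iz)
        else:
            resolutions.append(res)
    if resolutions:
        mean = float(np.mean(resolutions))
        sem = float(np.std(resolutions, ddof=1) / np.sqrt(len(resolutions))) if len(resolutions) > 1 else 0.0
    else:
        mean, sem = float("nan"), float("nan")
    return FrcResult(
        resolutions_nm=resolutions,
        mean_nm=mean,
        sem_nm=sem,
        curves=curves,
        unresolved_planes=unresolved,
    )


def bead_fwhm_resolution(
    bead_locs: pd.DataFrame,
    group_column: str = "bead_id",
    *,
    min_locs: int = 30,
    tilt_limit_deg: float = 30.0,
) -> BeadResolution:
    """FWHM resolution from fiducial localization clusters.

    For each bead (grouped by ``group_column``) with at least ``min_locs``
    localizations, the 3D point cloud is projected on its principal axes;
    FWHM along an axis is 2.35 × the standard deviation of the projections.
    Lateral FWHM is the mean of the two short axes, axial the long axis
    (astigmatic localization is least precise along z); beads whose long
    axis deviates more than ``tilt_limit_deg`` from z are flagged.
    """
    lat, ax, axes_list, tilted = [], [], [], []
    for bead_id, grp in bead_locs.groupby(group_column):
        if len(grp) < min_locs:
            continue
        pts = grp[["x_nm", "y_nm", "z_nm"]].to_numpy(dtype=float)
        pts = pts - pts.mean(axis=0)
        cov = np.cov(pts.T)
        evals, evecs = np.linalg.eigh(cov)  # ascending
        stds = np.sqrt(np.maximum(evals, 0.0))
        fwhm = GAUSSIAN_FWHM_FACTOR * stds
        lat.append(float(np.mean(fwhm[:2])))
        ax.append(float(fwhm[2]))
        axes_list.append(evecs)
        long_axis = evecs[:, 2]
        tilt = np.degrees(np.arccos(np.clip(abs(long_axis[2]), 0, 1)))
        if tilt > tilt_limit_deg:
            tilted.append(bead_id)
    lat_arr = np.asarray(lat)
    ax_arr = np.asarray(ax)
    n = len(lat_arr)
    res = BeadResolution(
        lateral_fwhm_nm=lat_arr,
        axial_fwhm_nm=ax_arr,
        axes=axes_list,
        n_beads=n,
        tilted_beads=tilted,
    )
    if n:
        res.mean_lateral_nm = float(lat_arr.mean())
        res.mean_axial_nm = float(ax_arr.mean())
        if n > 1:
            res.sem_lateral_nm = float(lat_arr.std(ddof=1) / np.sqrt(n))
            res.sem_axial_nm = float(ax_arr.std(ddof=1) / np.sqrt(n))
    return res
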