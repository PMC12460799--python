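"""Offline volume reconstruction from per-plane localization tables.

Three steps follow the plane-by-plane acquisition: (1) residual drift in
each plane is corrected offline by subtracting the smoothed trajectory of
that plane's reference fiducial; (2) adjacent planes are registered
laterally using the mean shift of fiducials visible in both; (3) each
plane's localizations receive a vertical offset of (i−1)·Δz and the tables
are merged.  The merged volume can be rendered as a 3D Gaussian density
stack and cleaned of periodic camera-pixel grid artifacts in Fourier space.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .smartrack import BeadTrack

__all__ = [
    "PlaneLocalizations",
    "RenderConfig",
    "correct_residual_drift",
    "register_planes",
    "assemble_volume",
    "axial_cv",
    "render_volume",
    "remove_grid_artifact",
]

logger = logging.getLogger(__name__)


@dataclass
class PlaneLocalizations:
    """Filtered localizations of one plane plus its fiducial bookkeeping."""

    plane_index: int
    localizations: pd.DataFrame
    bead_track: BeadTrack | None = None
    fiducial_localizations: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if len(self.localizations) and "plane_index" in self.localizations:
            planes = self.localizations["plane_index"].unique()
            if not (len(planes) == 1 and planes[0] == self.plane_index):
                raise ValueError("localizations carry a different plane_index")


@dataclass
class RenderConfig:
    """Rendering grid: 10 nm lateral pixels, 200 nm plane spacing, Gaussian
    blur of 10 nm lateral and 50 nm axial."""

    sr_pixel_nm: float = 10.0
    plane_spacing_nm: float = 200.0
    blur_lateral_nm: float = 10.0
    blur_axial_nm: float = 50.0
    camera_pixel_nm: float = 108.0

    def __post_init__(self) -> None:
        if self.sr_pixel_nm <= 0:
            raise ValueError("sr_pixel_nm must be > 0")
        if self.zoom <= 1:
            raise ValueError("zoom factor must exceed 1")

    @property
    def zoom(self) -> float:
        """Super-resolution zoom z_sr = camera pixel / rendering pixel."""
        return self.camera_pixel_nm / self.sr_pixel_nm


def _smoothed_bead_displacement(track: BeadTrack, window: int) -> pd.DataFrame:
    pos = np.array(track.positions_nm, dtype=float)
    ref = np.asarray(track.reference_nm)
    disp = pos - ref
    smooth = pd.DataFrame(disp, columns=["dx", "dy", "dz"]).rolling(
        window, min_periods=1
    ).mean()
    smooth["frame"] = track.frames
    return smooth


def correct_residual_drift(
    plane: PlaneLocalizations, window: int | None = None
) -> PlaneLocalizations:
    """Subtract the reference bead's smoothed trajectory from a plane.

    The bead displacement from its reference position is moving-averaged
    (window defaults to the feedback averaging window) and linearly
    interpolated at each localization's frame, then subtracted from its
    coordinates.  Planes without a track pass through with a warning.
    """
    if plane.bead_track is None or len(plane.bead_track.positions_nm) == 0:
        logger.warning("plane %d: no bead track, skipped", plane.plane_index)
        return plane
    track = plane.bead_track
    if window is None:
        window = track.averaging_window
    smooth = _smoothed_bead_displacement(track, window)
    # zero-mean the correction so the bead's own corrected trajectory is
    # centered (a constant offset belongs to plane registration, not drift)
    for axis in ("dx", "dy", "dz"):
        smooth[axis] -= smooth[axis].mean()

    def corrected(df: pd.DataFrame) -> pd.DataFrame:
        if df is None or len(df) == 0:
            return df
        out = df.copy()
        fr = out["frame"].to_numpy(dtype=float)
        dx = np.interp(fr, smooth["frame"], smooth["dx"])
        dy = np.interp(fr, smooth["frame"], smooth["dy"])
        dz = np.interp(fr, smooth["frame"], smooth["dz"])
        out["x_nm"] = out["x_nm"] - dx
        out["y_nm"] = out["y_nm"] - dy
        out["z_um"] = out["z_um"] - dz / 1000.0
        return out

    return PlaneLocalizations(
        plane_index=plane.plane_index,
        localizations=corrected(plane.localizations),
        bead_track=track,
        fiducial_localizations=corrected(plane.fiducial_localizations),
    )


def register_planes(
    beads_i: pd.DataFrame,
    beads_iplus1: pd.DataFrame,
    *,
    match_radius_nm: float = 500.0,
) -> tuple[float, float]:
    """Lateral shift of plane i+1 relative to plane i from shared fiducials.

    Bead positions (columns ``x_nm``, ``y_nm``, one row per bead, e.g. the
    per-plane mean position of each fiducial) are matched between planes by
    nearest neighbor within ``match_radius_nm``; the returned shift is the
    mean of (position in plane i − position in plane i+1), to be *added* to
    plane i+1 coordinates.  Fewer than 2 shared beads is an error.
    """
    if len(beads_i) == 0 or len(beads_iplus1) == 0:
        raise ValueError("registration impossible: empty bead table")
    pi = beads_i[["x_nm", "y_nm"]].to_numpy(dtype=float)
    pj = beads_iplus1[["x_nm", "y_nm"]].to_numpy(dtype=float)
    tree = cKDTree(pj)
    dist, idx = tree.query(pi, distance_upper_bound=match_radius_nm)
    ok = np.isfinite(dist)
    if np.count_nonzero(ok) < 2:
        raise ValueError("registration impossible: fewer than 2 shared fiducials")
    shifts = pi[ok] - pj[idx[ok]]
    dx, dy = shifts.mean(axis=0)
    return float(dx), float(dy)


def assemble_volume(
    planes: list[PlaneLocalizations],
    dz_nm: float,
    *,
    register: bool = True,
    match_radius_nm: float = 500.0,
) -> pd.DataFrame:
    """Register (optionally) and merge planes into one localization table.

    Plane i+1 is translated laterally by the accumulated registration shift;
    every localization of plane index i receives a vertical offset of
    (i−1)·Δz so that ``z_nm = z_um·1000 + (plane_index−1)·Δz``.  Output
    ``loc_id`` is globally unique and sequential.
    """
    if not planes:
        raise ValueError("no planes to assemble")
    planes = sorted(planes, key=lambda p: p.plane_index)
    merged = []
    shift = np.zeros(2)
    prev_beads = None
    for plane in planes:
        if register and prev_beads is not None and plane.fiducial_localizations is not None:
            beads_now = _mean_bead_positions(plane.fiducial_localizations)
            dx, dy = register_planes(prev_beads, beads_now, match_radius_nm=match_radius_nm)
            shift = shift + np.array([dx, dy])
        df = plane.localizations.copy()
        df["x_nm"] = df["x_nm"] + shift[0]
        df["y_nm"] = df["y_nm"] + shift[1]
        df["z_nm"] = df["z_um"] * 1000.0 + (plane.plane_index - 1) * dz_nm
        merged.append(df)
        if plane.fiducial_localizations is not None:
            shifted = plane.fiducial_localizations.copy()
            shifted["x_nm"] += shift[0]
            shifted["y_nm"] += shift[1]
            prev_beads = _mean_bead_positions(shifted)
    out = pd.concat(merged, ignore_index=True)
    out["loc_id"] = np.arange(len(out))
    return out


def _mean_bead_positions(fid_locs: pd.DataFrame) -> pd.DataFrame:
    """Mean position per bead over a whole plane acquisition."""
    if "bead_id" in fid_locs.columns:
        return fid_locs.groupby("bead_id", as_index=False)[["x_nm", "y_nm"]].mean()
    return fid_locs[["x_nm", "y_nm"]]


def axial_cv(volume: pd.DataFrame, bin_nm: float = 200.0) -> float:
    """Coefficient of variation of localization counts along z.

    Counts are histogrammed in bins of ``bin_nm`` over the occupied z range;
    CV = population std / mean of the per-bin counts.
    """
    if len(volume) == 0:
        raise ValueError("empty volume")
    z = volume["z_nm"].to_numpy(dtype=float)
    lo = z.min()
    idx = np.floor((z - lo) / bin_nm).astype(int)
    counts = np.bincount(idx)
    if len(counts) < 2:
        raise ValueError("need at least 2 populated bins")
    return float(np.std(counts) / np.mean(counts))


def render_volume(
    volume: pd.DataFrame,
    cfg: RenderConfig,
    *,
    origin_nm: tuple[float, float, float] | None = None,
    shape: tuple[int, int, int] | None = None,
) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Render localizations as a blurred 3D density stack (z, y, x).

    Each localization contributes a 3D Gaussian (σ = 10 nm lateral, 50 nm
    axial by default) on a grid of ``sr_pixel_nm`` laterally and
    ``plane_spacing_nm`` axially.  Implemented as a histogram deposit
    followed by a Gaussian filter; total intensity equals the localization
    count.  ``origin_nm``/``shape`` pin the grid explicitly (e.g. to render
    two half-datasets on identical grids); by default they cover the data
    with a 3σ margin.  Returns ``(stack, origin_nm)`` with the origin at
    the center of voxel [0, 0, 0] in (x, y, z) order.
    """
    if len(volume) == 0 and shape is None:
        return np.zeros((1, 1, 1), dtype=np.float32), (0.0, 0.0, 0.0)
    x = volume["x_nm"].to_numpy(dtype=float)
    y = volume["y_nm"].to_numpy(dtype=float)
    z = volume["z_nm"].to_numpy(dtype=float)
    px, pz = cfg.sr_pixel_nm, cfg.plane_spacing_nm
    pad = 3 * cfg.blur_lateral_nm
    if origin_nm is None:
        origin_nm = (x.min() - pad, y.min() - pad, z.min() - 3 * cfg.blur_axial_nm)
    x0, y0, z0 = origin_nm
    ix = np.round((x - x0) / px).astype(int)
    iy = np.round((y - y0) / px).astype(int)
    iz = np.round((z - z0) / pz).astype(int)
    if shape is None:
        shape = (
            iz.max() + 1 + 3,
            iy.max() + 1 + int(pad / px),
            ix.max() + 1 + int(pad / px),
        )
    stack = np.zeros(shape, dtype=np.float32)
    ok = (
        (ix >= 0) & (ix < shape[2]) & (iy >= 0) & (iy < shape[1]) & (iz >= 0) & (iz < shape[0])
    )
    np.add.at(stack, (iz[ok], iy[ok], ix[ok]), 1.0)
    sig = (cfg.blur_axial_nm / pz, cfg.blur_lateral_nm / px, cfg.blur_lateral_nm / px)
    stack = ndimage.gaussian_filter(stack, sigma=sig, mode="constant")
    return stack, (x0, y0, z0)


def remove_grid_artifact(
    image: np.ndarray, camera_pixel_nm: float, zoom: float
) -> np.ndarray:
    """Suppress the periodic camera-pixel grid artifact of a rendered image.

    In the 2D discrete Fourier transform of a rendered image whose pixel
    pitch is ``camera_pixel_nm / zoom``, the grid artifact sits at spatial
    frequency 1/Δ (Δ = camera pixel) and its harmonics, i.e. at bin indices
    that are integer nonzero multiples of N/zoom along each axis.  Those
    rows and columns are set to zero (DC excluded) and the filtered image is
    returned (real part of the inverse transform).
    """
    if zoom <= 1:
        raise ValueError("zoom factor must exceed 1")
    image = np.asarray(image, dtype=float)
    ny, nx = image.shape
    if min(ny, nx) / zoom < 1:
        raise ValueError("image too small for the grid frequency")
    spec = np.fft.fft2(image)

    def grid_bins(n: int) -> np.ndarray:
        step = n / zoom
        m_max = int(np.floor((n / 2) / step))
        bins = []
        for m in range(1, m_max + 1):
            k = int(round(m * step))
            if 0 < k < n:
                bins.extend([k, (n - k) % n])
        return np.unique([b for b in bins if b != 0])

    ky = grid_bins(ny)
    kx = grid_bins(nx)
    spec[ky, :] = 0.0
    spec[:, kx] = 0.0
    return np.real(np.fft.ifft2(spec))
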