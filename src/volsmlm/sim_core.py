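"""Forward model for synthetic astigmatic SMLM acquisitions.

The simulator produces multi-frame camera stacks with known ground truth,
emulating the physics of a light-sheet 3D SMLM experiment:

* a scalar Fourier-optics PSF: the pupil carries Zernike aberrations
  (nm RMS, Noll-normalized), an induced astigmatism used for axial encoding,
  a depth-proportional first-order spherical term (refractive-index
  mismatch), and exact high-NA defocus for the emitter's axial offset;
* DNA-PAINT-style two-state blinking (discrete-time Markov chain per frame);
* photostable fiducial beads placed at a given volumetric density around an
  excluded sample well;
* rigid three-axis mechanical drift applied to the sample;
* an sCMOS camera model (quantum efficiency, e-/ADU conversion, baseline
  offset, Gaussian read noise, 16-bit quantization).

Coordinates: x, y in nm with the origin at the corner pixel center
(pixel-center convention); z in µm, positive away from the coverslip;
frames are 0-based.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from .zernike import ZernikeCoeffs

__all__ = [
    "OpticalConfig",
    "CameraModel",
    "Emitter",
    "BlinkKinetics",
    "DriftTrajectory",
    "FrameStack",
    "effective_coefficients",
    "render_psf",
    "pupil_phase",
    "simulate_acquisition",
    "place_fiducials",
    "apply_camera",
]


@dataclass(frozen=True)
class OpticalConfig:
    """Optical system parameters.

    ``depth_spherical_slope_rad_per_um`` is the rate at which first-order
    spherical aberration (in rad RMS of pupil phase) accumulates per µm of
    imaging depth due to residual index mismatch.
    """

    numerical_aperture: float = 1.2
    wavelength_nm: float = 580.0
    pixel_size_camera_nm: float = 108.0
    pupil_grid_size: int = 256
    depth_spherical_slope_rad_per_um: float = 0.031
    immersion_index: float = 1.33
    oversample: int = 3
    #: Gaussian blur emulating finite emitter size (~100 nm fiducials) and
    #: residual incoherent system blur, in nm; applied to the PSF intensity.
    system_blur_nm: float = 85.0

    def __post_init__(self) -> None:
        if self.numerical_aperture <= 0:
            raise ValueError("numerical_aperture must be > 0")
        if self.wavelength_nm <= 0:
            raise ValueError("wavelength_nm must be > 0")
        if self.pupil_grid_size < 64 or self.pupil_grid_size % 2:
            raise ValueError("pupil_grid_size must be even and >= 64")
        if self.numerical_aperture >= self.immersion_index:
            raise ValueError("numerical_aperture must be below immersion index")


@dataclass(frozen=True)
class CameraModel:
    """sCMOS camera: photons -> A/D counts."""

    baseline_adu: float = 100.0
    electrons_per_adu: float = 0.46
    quantum_efficiency: float = 0.82
    read_noise_e: float = 1.4

    def __post_init__(self) -> None:
        if self.baseline_adu < 0:
            raise ValueError("baseline_adu must be >= 0")
        if not 0 < self.quantum_efficiency <= 1:
            raise ValueError("quantum_efficiency must be in (0, 1]")
        if self.electrons_per_adu <= 0:
            raise ValueError("electrons_per_adu must be > 0")

    def adu_per_photon(self) -> float:
        return self.quantum_efficiency / self.electrons_per_adu

    def photons_for_signal_adu(self, signal_adu: float) -> float:
        """Mean photons per frame producing ``signal_adu`` integrated counts."""
        return signal_adu / self.adu_per_photon()


@dataclass
class Emitter:
    """One point emitter; ``z_um`` is relative to the current focal plane."""

    x_nm: float
    y_nm: float
    z_um: float
    photons_mean: float
    kind: str = "molecule"  # molecule | fiducial

    def __post_init__(self) -> None:
        if self.photons_mean <= 0:
            raise ValueError("photons_mean must be > 0")
        if self.kind not in ("molecule", "fiducial"):
            raise ValueError(f"unknown emitter kind {self.kind!r}")


@dataclass(frozen=True)
class BlinkKinetics:
    """Two-state (ON/OFF) discrete-time blinking kinetics.

    ``on_rate_per_frame`` is the OFF->ON probability per frame (proportional
    to imager concentration in DNA-PAINT); the ON->OFF probability is
    ``1 / mean_on_frames``.
    """

    on_rate_per_frame: float = 2e-3
    mean_on_frames: float = 3.0

    def __post_init__(self) -> None:
        if self.on_rate_per_frame <= 0 or self.mean_on_frames <= 0:
            raise ValueError("kinetic rates must be > 0")

    @property
    def off_rate_per_frame(self) -> float:
        return 1.0 / self.mean_on_frames

    @property
    def steady_state_on_fraction(self) -> float:
        return self.on_rate_per_frame / (
            self.on_rate_per_frame + self.off_rate_per_frame
        )


@dataclass
class DriftTrajectory:
    """Per-frame rigid sample offsets in nm (applied to the emitters)."""

    dx_nm: np.ndarray
    dy_nm: np.ndarray
    dz_nm: np.ndarray

    def __post_init__(self) -> None:
        self.dx_nm = np.asarray(self.dx_nm, dtype=float)
        self.dy_nm = np.asarray(self.dy_nm, dtype=float)
        self.dz_nm = np.asarray(self.dz_nm, dtype=float)
        if not (len(self.dx_nm) == len(self.dy_nm) == len(self.dz_nm)):
            raise ValueError("drift axes must have equal length")

    def __len__(self) -> int:
        return len(self.dx_nm)

    @classmethod
    def zero(cls, n_frames: int) -> "DriftTrajectory":
        z = np.zeros(n_frames)
        return cls(z.copy(), z.copy(), z.copy())

    @classmethod
    def linear(
        cls, n_frames: int, total_nm: tuple[float, float, float]
    ) -> "DriftTrajectory":
        t = np.arange(n_frames) / max(n_frames - 1, 1)
        return cls(t * total_nm[0], t * total_nm[1], t * total_nm[2])


@dataclass
class FrameStack:
    """A simulated plane acquisition plus its ground truth."""

    frames: np.ndarray  # (n_frames, ny, nx) uint16 A/D counts
    frame_rate_hz: float
    plane_index: int
    ground_truth: pd.DataFrame  # frame, id, kind, x_nm, y_nm, z_um, photons
    drift: DriftTrajectory

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def save(self, tiff_path: str | Path, truth_csv_path: str | Path | None = None) -> None:
        tifffile.imwrite(str(tiff_path), self.frames.astype(np.uint16))
        if truth_csv_path is not None:
            self.ground_truth.to_csv(truth_csv_path, index=False)


# ---------------------------------------------------------------------------
# Pupil geometry / PSF rendering
# ---------------------------------------------------------------------------


@functools.lru_cache(maxsize=8)
def _pupil_geometry(cfg: OpticalConfig):
    """Frequency-space pupil grids for a configuration (cached)."""
    n = cfg.pupil_grid_size
    dx = cfg.pixel_size_camera_nm / cfg.oversample  # fine image sampling, nm
    f = np.fft.fftfreq(n, d=dx)  # nm^-1
    fx, fy = np.meshgrid(f, f)  # fy varies along rows (y axis)
    fr = np.hypot(fx, fy)
    f_max = cfg.numerical_aperture / cfg.wavelength_nm
    mask = fr <= f_max
    rho = np.where(mask, fr / f_max, 0.0)
    theta = np.arctan2(fy, fx)
    # Exact defocus: longitudinal wavevector component per nm of axial offset,
    # referenced to the chief ray so phase values stay small.
    n_imm = cfg.immersion_index
    kz = 2 * np.pi * (
        np.sqrt(np.maximum((n_imm / cfg.wavelength_nm) ** 2 - fr**2, 0.0))
        - n_imm / cfg.wavelength_nm
    )
    return mask, rho, theta, fx, fy, kz


def effective_coefficients(
    coeffs: ZernikeCoeffs, depth_um: float, cfg: OpticalConfig
) -> ZernikeCoeffs:
    """Add the depth-proportional spherical aberration to ``coeffs``.

    The slope is stated in rad RMS of pupil phase per µm of depth and is
    converted to nm RMS of optical path via λ / 2π.
    """
    if depth_um < 0:
        raise ValueError("depth_um must be >= 0")
    extra_nm = (
        depth_um
        * cfg.depth_spherical_slope_rad_per_um
        * cfg.wavelength_nm
        / (2 * np.pi)
    )
    return coeffs.with_mode("spherical", coeffs.get("spherical") + extra_nm)


def pupil_phase(
    coeffs: ZernikeCoeffs, z_um: float, depth_um: float, cfg: OpticalConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Pupil phase map (rad) and pupil mask for given aberrations and defocus."""
    mask, rho, theta, _, _, kz = _pupil_geometry(cfg)
    eff = effective_coefficients(coeffs, depth_um, cfg)
    w_nm = eff.wavefront_nm(rho, theta)
    phase = 2 * np.pi / cfg.wavelength_nm * w_nm + kz * (z_um * 1000.0)
    return np.where(mask, phase, 0.0), mask


def render_psf(
    coeffs: ZernikeCoeffs,
    z_um: float,
    depth_um: float,
    cfg: OpticalConfig,
    *,
    size_px: int = 21,
    shift_nm: tuple[float, float] = (0.0, 0.0),
) -> np.ndarray:
    """Render the camera-sampled PSF intensity, normalized to unit sum.

    Parameters
    ----------
    coeffs
        Zernike aberrations (nm RMS); a depth-proportional spherical term is
        added on top of the explicit coefficients.
    z_um
        Axial offset of the emitter from the focal plane (|z| <= 2 µm).
    depth_um
        Imaging depth above the coverslip (>= 0).
    size_px
        Side of the returned square patch in camera pixels (odd).
    shift_nm
        Lateral (x, y) subpixel shift of the PSF center, applied as a pupil
        tilt; the unshifted center is the patch center pixel.
    """
    if abs(z_um) > 2.0:
        raise ValueError("|z_um| must be <= 2 µm")
    if size_px % 2 == 0:
        raise ValueError("size_px must be odd")
    mask, rho, theta, fx, fy, kz = _pupil_geometry(cfg)
    phase, _ = pupil_phase(coeffs, z_um, depth_um, cfg)
    tilt = 2 * np.pi * (fx * shift_nm[0] + fy * shift_nm[1])
    pupil = mask * np.exp(1j * (phase + tilt))
    field = np.fft.fftshift(np.fft.fft2(pupil))
    psf_fine = np.abs(field) ** 2
    if cfg.system_blur_nm > 0:
        from scipy import ndimage

        dx_fine = cfg.pixel_size_camera_nm / cfg.oversample
        psf_fine = ndimage.gaussian_filter(
            psf_fine, cfg.system_blur_nm / dx_fine, mode="constant"
        )
    os = cfg.oversample
    half = (size_px * os) // 2
    c = cfg.pupil_grid_size // 2
    if half > c:
        raise ValueError("size_px too large for the pupil grid")
    crop = psf_fine[c - half : c + half + 1, c - half : c + half + 1]
    # bin oversampled grid to camera pixels (odd oversample keeps centering)
    crop = crop[: size_px * os, : size_px * os]
    binned = crop.reshape(size_px, os, size_px, os).sum(axis=(1, 3))
    total = binned.sum()
    if total <= 0:
        raise RuntimeError("empty PSF render")
    return binned / total


# ---------------------------------------------------------------------------
# Camera
# ---------------------------------------------------------------------------


def apply_camera(
    photon_image: np.ndarray,
    camera: CameraModel,
    rng: np.random.Generator | None = None,
    *,
    shot_noise: bool = True,
) -> np.ndarray:
    """Convert an expected-photon image to quantized A/D counts."""
    photons = np.asarray(photon_image, dtype=float)
    if np.any(photons < 0):
        raise ValueError("photon image must be non-negative")
    mean_e = photons * camera.quantum_efficiency
    if shot_noise:
        if rng is None:
            raise ValueError("rng required for shot noise")
        electrons = rng.poisson(mean_e).astype(float)
    else:
        electrons = mean_e
    if camera.read_noise_e > 0:
        if rng is None:
            raise ValueError("rng required for read noise")
        electrons = electrons + rng.normal(0.0, camera.read_noise_e, electrons.shape)
    adu = electrons / camera.electrons_per_adu + camera.baseline_adu
    return np.clip(np.rint(adu), 0, 65535).astype(np.uint16)


# ---------------------------------------------------------------------------
# Acquisition simulation
# ---------------------------------------------------------------------------


def _add_patch(image: np.ndarray, patch: np.ndarray, cx_px: int, cy_px: int) -> None:
    """Add ``patch`` centered at pixel (cx, cy), clipping at the borders."""
    half = patch.shape[0] // 2
    ny, nx = image.shape
    x0, x1 = cx_px - half, cx_px + half + 1
    y0, y1 = cy_px - half, cy_px + half + 1
    px0, py0 = max(0, -x0), max(0, -y0)
    px1 = patch.shape[1] - max(0, x1 - nx)
    py1 = patch.shape[0] - max(0, y1 - ny)
    if px0 >= px1 or py0 >= py1:
        return
    image[max(0, y0) : min(ny, y1), max(0, x0) : min(nx, x1)] += patch[
        py0:py1, px0:px1
    ]


def simulate_acquisition(
    emitters: Sequence[Emitter],
    kinetics: BlinkKinetics,
    drift: DriftTrajectory,
    coeffs: ZernikeCoeffs,
    camera: CameraModel,
    n_frames: int,
    cfg: OpticalConfig,
    seed: int,
    *,
    img_shape: tuple[int, int] = (64, 64),
    depth_um: float = 0.0,
    background_adu: float = 0.0,
    background_gradient_adu: tuple[float, float] | None = None,
    frame_rate_hz: float = 10.0,
    plane_index: int = 1,
    psf_size_px: int = 15,
    shot_noise: bool = True,
) -> FrameStack:
    """Simulate a blinking single-molecule acquisition of one plane.

    Molecules blink following ``kinetics`` (fiducials are always ON); the
    whole sample is rigidly shifted by ``drift`` frame by frame; the optical
    model renders each ON emitter's aberrated astigmatic PSF; the camera
    model adds noise and quantizes.  ``background_adu`` is a flat background
    (in counts above baseline); ``background_gradient_adu`` optionally adds a
    smooth linear ramp (counts per pixel along x and y).

    Returns a :class:`FrameStack` whose ground truth lists every ON emitter
    per frame at its drifted position.
    """
    ny, nx = img_shape
    if ny <= 0 or nx <= 0:
        raise ValueError("empty frame geometry")
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if len(drift) != n_frames:
        raise ValueError("drift length must equal n_frames")
    rng = np.random.default_rng(seed)
    px = cfg.pixel_size_camera_nm
    adu_per_photon = camera.adu_per_photon()

    bg = np.full((ny, nx), background_adu / adu_per_photon, dtype=float)
    if background_gradient_adu is not None:
        gx, gy = background_gradient_adu
        xs = np.arange(nx)
        ys = np.arange(ny)[:, None]
        bg = bg + (gx * xs + gy * ys) / adu_per_photon

    molecules = [i for i, e in enumerate(emitters) if e.kind == "molecule"]
    on = np.zeros(len(emitters), dtype=bool)
    on[[i for i, e in enumerate(emitters) if e.kind == "fiducial"]] = True
    if molecules:
        on[molecules] = (
            rng.random(len(molecules)) < kinetics.steady_state_on_fraction
        )

    frames = np.empty((n_frames, ny, nx), dtype=np.uint16)
    truth_rows: list[tuple] = []
    for t in range(n_frames):
        if t > 0 and molecules:
            u = rng.random(len(molecules))
            for j, idx in enumerate(molecules):
                if on[idx]:
                    if u[j] < kinetics.off_rate_per_frame:
                        on[idx] = False
                elif u[j] < kinetics.on_rate_per_frame:
                    on[idx] = True
        photon_img = bg.copy()
        for idx, em in enumerate(emitters):
            if not on[idx]:
                continue
            x = em.x_nm + drift.dx_nm[t]
            y = em.y_nm + drift.dy_nm[t]
            z = em.z_um + drift.dz_nm[t] / 1000.0
            xpix = x / px
            ypix = y / px
            cx, cy = int(round(xpix)), int(round(ypix))
            margin = psf_size_px // 2
            if cx < -margin or cx >= nx + margin or cy < -margin or cy >= ny + margin:
                continue
            patch = render_psf(
                coeffs,
                float(np.clip(z, -2.0, 2.0)),
                depth_um,
                cfg,
                size_px=psf_size_px,
                shift_nm=((xpix - cx) * px, (ypix - cy) * px),
            )
            _add_patch(photon_img, em.photons_mean * patch, cx, cy)
            truth_rows.append((t, idx, em.kind, x, y, z, em.photons_mean))
        frames[t] = apply_camera(photon_img, camera, rng, shot_noise=shot_noise)

    truth = pd.DataFrame(
        truth_rows,
        columns=["frame", "id", "kind", "x_nm", "y_nm", "z_um", "photons"],
    )
    return FrameStack(
        frames=frames,
        frame_rate_hz=frame_rate_hz,
        plane_index=plane_index,
        ground_truth=truth,
        drift=drift,
    )


def place_fiducials(
    density_per_um3: float,
    volume_um3: tuple[float, float, float],
    well_box: tuple[tuple[float, float], tuple[float, float], tuple[float, float]]
    | None = None,
    seed: int = 0,
    *,
    photons_mean: float = 4000.0,
) -> list[Emitter]:
    """Place fiducial beads uniformly in a volume, excluding the sample well.

    The bead count is Poisson with mean ``density * (volume - well volume)``;
    positions are uniform outside ``well_box`` (axis-aligned, µm bounds).
    Returned emitter coordinates are x, y in nm and z in µm.
    """
    if density_per_um3 < 0:
        raise ValueError("density must be >= 0")
    lx, ly, lz = volume_um3
    vol = lx * ly * lz
    if well_box is not None:
        (wx0, wx1), (wy0, wy1), (wz0, wz1) = well_box
        if not (0 <= wx0 <= wx1 <= lx and 0 <= wy0 <= wy1 <= ly and 0 <= wz0 <= wz1 <= lz):
            raise ValueError("well_box must lie inside the volume")
        vol -= (wx1 - wx0) * (wy1 - wy0) * (wz1 - wz0)
    rng = np.random.default_rng(seed)
    n = int(rng.poisson(density_per_um3 * vol))
    beads: list[Emitter] = []
    while len(beads) < n:
        x = rng.uniform(0, lx)
        y = rng.uniform(0, ly)
        z = rng.uniform(0, lz)
        if well_box is not None:
            (wx0, wx1), (wy0, wy1), (wz0, wz1) = well_box
            if wx0 <= x <= wx1 and wy0 <= y <= wy1 and wz0 <= z <= wz1:
                continue
        beads.append(
            Emitter(
                x_nm=x * 1000.0,
                y_nm=y * 1000.0,
                z_um=z,
                photons_mean=photons_mean,
                kind="fiducial",
            )
        )
    return beads
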