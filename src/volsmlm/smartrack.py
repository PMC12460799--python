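"""Real-time fiducial tracking, feedback drift correction, plane sequencing.

One fiducial bead per plane is selected from a pre-acquisition image (in
focus, well-fitted, outside the sample well), then tracked frame by frame.
The drift at frame i is the Euclidean distance between the bead's current
(temporally averaged) position and its reference position at the start of
the plane; whenever it exceeds a user threshold, the opposite displacement
is sent to a simulated three-axis stage.  A multi-plane acquisition plan
advances the focal plane by a fixed z-step after each plane; planes without
an eligible bead are skipped and logged.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import sim_core
from .localizer import AstigCalibration, assign_z, fit_gaussian, localize_stack
from .sim_core import (
    BlinkKinetics,
    CameraModel,
    DriftTrajectory,
    Emitter,
    FrameStack,
    OpticalConfig,
)
from .zernike import ZernikeCoeffs

__all__ = [
    "BeadTrack",
    "AcquisitionPlan",
    "select_fiduciary",
    "compute_drift",
    "FeedbackController",
    "simulate_feedback_loop",
    "SimulatedScene",
    "run_volume_acquisition",
]

logger = logging.getLogger(__name__)


@dataclass
class BeadTrack:
    """Time series of one fiducial used for feedback and offline correction."""

    bead_id: int
    reference_nm: tuple[float, float, float]
    frames: list[int] = field(default_factory=list)
    positions_nm: list[tuple[float, float, float]] = field(default_factory=list)
    drifts_nm: list[float] = field(default_factory=list)
    corrections: list[tuple[int, float, float, float]] = field(default_factory=list)
    averaging_window: int = 10
    plane_index: int = 1

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "plane": self.plane_index,
                "frame": self.frames,
                "bead_id": self.bead_id,
                "x_nm": [p[0] for p in self.positions_nm],
                "y_nm": [p[1] for p in self.positions_nm],
                "z_nm": [p[2] for p in self.positions_nm],
                "d_nm": self.drifts_nm,
            }
        )
        corr = {f: (dx, dy, dz) for f, dx, dy, dz in self.corrections}
        df["corr_x_nm"] = [corr.get(f, (0.0, 0.0, 0.0))[0] for f in self.frames]
        df["corr_y_nm"] = [corr.get(f, (0.0, 0.0, 0.0))[1] for f in self.frames]
        df["corr_z_nm"] = [corr.get(f, (0.0, 0.0, 0.0))[2] for f in self.frames]
        return df


@dataclass
class AcquisitionPlan:
    """Multi-plane acquisition parameters."""

    first_plane_z_um: float
    n_planes: int
    dz_nm: float
    frames_per_plane: int
    well_box_nm: tuple[tuple[float, float], tuple[float, float]] | None = None
    drift_threshold_nm: float = 0.0

    def __post_init__(self) -> None:
        if self.n_planes < 1:
            raise ValueError("n_planes must be >= 1")
        if self.dz_nm <= 0:
            raise ValueError("dz_nm must be > 0")


def _outside_well(
    x_nm: np.ndarray,
    y_nm: np.ndarray,
    well_box_nm: tuple[tuple[float, float], tuple[float, float]] | None,
) -> np.ndarray:
    if well_box_nm is None:
        return np.ones_like(np.asarray(x_nm, dtype=float), dtype=bool)
    (x0, x1), (y0, y1) = well_box_nm
    inside = (x_nm >= x0) & (x_nm <= x1) & (y_nm >= y0) & (y_nm <= y1)
    return ~inside


def select_fiduciary(
    locs: pd.DataFrame,
    well_box_nm: tuple[tuple[float, float], tuple[float, float]] | None = None,
    *,
    sigma_min_nm: float = 130.0,
    sigma_max_nm: float = 300.0,
    chi2_min: float = 0.65,
) -> pd.Series | None:
    """Pick the reference bead for a plane, or None if no candidate.

    Candidates must be close to focus (130 ≤ σx, σy ≤ 300 nm), well fitted
    (χ² > 0.65), and lie outside the sample well.  Among candidates the one
    with minimal |σx − σy| (axially closest to the imaging plane) is chosen,
    ties broken by the highest χ².
    """
    if len(locs) == 0:
        return None
    ok = (
        locs["sigma_x_nm"].between(sigma_min_nm, sigma_max_nm)
        & locs["sigma_y_nm"].between(sigma_min_nm, sigma_max_nm)
        & (locs["chi2"] > chi2_min)
        & _outside_well(
            locs["x_nm"].to_numpy(), locs["y_nm"].to_numpy(), well_box_nm
        )
    )
    candidates = locs.loc[ok]
    if len(candidates) == 0:
        return None
    anis = (candidates["sigma_x_nm"] - candidates["sigma_y_nm"]).abs()
    best = candidates.assign(_anis=anis).sort_values(
        ["_anis", "chi2"], ascending=[True, False]
    )
    return best.iloc[0].drop(labels="_anis")


def compute_drift(
    p0: tuple[float, float, float], pi: tuple[float, float, float]
) -> float:
    """Euclidean drift distance d_i between reference and current position."""
    p0 = np.asarray(p0, dtype=float)
    pi = np.asarray(pi, dtype=float)
    if not (np.all(np.isfinite(p0)) and np.all(np.isfinite(pi))):
        raise ValueError("non-finite coordinates")
    return float(np.linalg.norm(pi - p0))


class FeedbackController:
    """Stateful feedback loop on one bead: sliding average, threshold, abort.

    The reference position stays absolute for the whole plane; corrections
    accumulate.  ``max_misses`` consecutive frames without a bead
    localization abort the plane.
    """

    def __init__(
        self,
        reference_nm: tuple[float, float, float],
        threshold_nm: float = 0.0,
        window: int = 10,
        max_misses: int = 50,
        plane_index: int = 1,
        bead_id: int = 0,
    ) -> None:
        self.track = BeadTrack(
            bead_id=bead_id,
            reference_nm=tuple(float(v) for v in reference_nm),
            averaging_window=window,
            plane_index=plane_index,
        )
        self.threshold_nm = threshold_nm
        self.window = window
        self.max_misses = max_misses
        self._recent: deque[np.ndarray] = deque(maxlen=window)
        self._stage = np.zeros(3)  # cumulative corrections issued so far
        self._misses = 0
        self.aborted = False

    def step(
        self, frame: int, loc_nm: tuple[float, float, float] | None
    ) -> tuple[float, float, float] | None:
        """Process one frame's bead localization; return a stage correction.

        ``loc_nm`` is the bead position as localized in the current frame
        (i.e. including the stage corrections applied so far) or None for a
        lost bead.  Localizations are compensated by the controller's own
        correction ledger before temporal averaging, so the sliding window
        estimates the underlying drift rather than a mixture of pre- and
        post-correction positions (which would make the loop oscillate).
        When the estimated current displacement from the reference exceeds
        the threshold, the move bringing the bead back is returned.
        """
        if loc_nm is None:
            self._misses += 1
            if self._misses >= self.max_misses:
                self.aborted = True
            return None
        self._misses = 0
        p = np.asarray(loc_nm, dtype=float)
        self._recent.append(p - self._stage)  # drift-space position
        drift_est = np.mean(np.stack(self._recent), axis=0) - np.asarray(
            self.track.reference_nm
        )
        # estimated current apparent displacement from the reference
        pending = drift_est + self._stage
        d = float(np.linalg.norm(pending))
        self.track.frames.append(frame)
        self.track.positions_nm.append(tuple(p))
        self.track.drifts_nm.append(d)
        if d > self.threshold_nm:
            move = -pending
            self._stage = self._stage + move
            self.track.corrections.append((frame, *move))
            return tuple(move)
        return None


def simulate_feedback_loop(
    drift: DriftTrajectory,
    precision_nm: tuple[float, float, float] = (6.0, 6.0, 12.0),
    window: int = 10,
    threshold_nm: float = 0.0,
    seed: int = 0,
    *,
    stage_noise_nm: float = 0.0,
    latency_frames: int = 1,
) -> dict:
    """Closed-loop simulation of the feedback on a bead observation model.

    The bead's apparent position at frame i is ``reference + drift_i +
    stage_i``; its localization adds white Gaussian noise with per-axis
    standard deviation ``precision_nm``.  Corrections act on the stage after
    ``latency_frames`` frames; the stage optionally adds Gaussian
    positioning noise per move.

    Returns a dict with the per-frame residual (apparent − reference, nm,
    shape (n, 3)), the summed corrections per axis, the final residual, and
    the :class:`BeadTrack`.
    """
    rng = np.random.default_rng(seed)
    n = len(drift)
    ctrl = FeedbackController((0.0, 0.0, 0.0), threshold_nm, window)
    stage = np.zeros(3)
    pending: deque[tuple[int, np.ndarray]] = deque()
    residuals = np.empty((n, 3))
    total_correction = np.zeros(3)
    d = np.stack([drift.dx_nm, drift.dy_nm, drift.dz_nm], axis=1)
    for i in range(n):
        while pending and pending[0][0] <= i:
            _, move = pending.popleft()
            noisy = move + (
                rng.normal(0.0, stage_noise_nm, 3) if stage_noise_nm > 0 else 0.0
            )
            stage += noisy
            total_correction -= noisy
        apparent = d[i] + stage
        residuals[i] = apparent
        observed = apparent + rng.normal(0.0, 1.0, 3) * np.asarray(precision_nm)
        corr = ctrl.step(i, tuple(observed))
        if corr is not None:
            pending.append((i + latency_frames, np.asarray(corr)))
    return {
        "residual_nm": residuals,
        "total_correction_nm": total_correction,
        "final_residual_nm": residuals[-1],
        "total_drift_nm": d[-1],
        "track": ctrl.track,
    }


@dataclass
class SimulatedScene:
    """Static description of a synthetic sample for multi-plane acquisition.

    Emitter z coordinates are absolute (µm above the coverslip); during the
    acquisition of a plane, each emitter's axial offset is its absolute z
    minus the plane's focal position.
    """

    molecules: list[Emitter]
    fiducials: list[Emitter]
    kinetics: BlinkKinetics
    coeffs: ZernikeCoeffs
    camera: CameraModel
    cfg: OpticalConfig
    img_shape: tuple[int, int] = (48, 48)
    depth_um: float = 0.0
    background_adu: float = 20.0
    drift_rate_nm_per_frame: tuple[float, float, float] = (0.0, 0.0, 0.0)
    z_visible_um: float = 0.6


def _acquire_plane(
    scene: SimulatedScene,
    plane_z_um: float,
    plane_index: int,
    n_frames: int,
    cal: AstigCalibration,
    ctrl: FeedbackController,
    bead: Emitter,
    drift_offset_nm: np.ndarray,
    rng: np.random.Generator,
) -> tuple[FrameStack, np.ndarray]:
    """Frame-by-frame closed-loop acquisition of one plane."""
    px = scene.cfg.pixel_size_camera_nm
    stage = np.zeros(3)
    pending: deque[tuple[int, np.ndarray]] = deque()
    frames = np.empty((n_frames, *scene.img_shape), dtype=np.uint16)
    truth_rows = []
    rate = np.asarray(scene.drift_rate_nm_per_frame)
    half_roi = 7
    on = rng.random(len(scene.molecules)) < scene.kinetics.steady_state_on_fraction
    drift_now = drift_offset_nm.copy()
    shifts = []
    for t in range(n_frames):
        while pending and pending[0][0] <= t:
            _, move = pending.popleft()
            stage += move
        if t > 0:
            drift_now = drift_now + rate
            if len(scene.molecules):
                u = rng.random(len(scene.molecules))
                on = np.where(
                    on,
                    u >= scene.kinetics.off_rate_per_frame,
                    u < scene.kinetics.on_rate_per_frame,
                )
        shift = drift_now + stage
        shifts.append(shift.copy())
        photon_img = np.full(
            scene.img_shape,
            scene.background_adu / scene.camera.adu_per_photon(),
            dtype=float,
        )
        visible = []
        for em_list, kind_on in ((scene.molecules, on), (scene.fiducials, None)):
            for j, em in enumerate(em_list):
                if kind_on is not None and not kind_on[j]:
                    continue
                z_rel = em.z_um - plane_z_um + shift[2] / 1000.0
                if abs(z_rel) > scene.z_visible_um:
                    continue
                x = em.x_nm + shift[0]
                y = em.y_nm + shift[1]
                cx, cy = int(round(x / px)), int(round(y / px))
                if not (0 <= cx < scene.img_shape[1] and 0 <= cy < scene.img_shape[0]):
                    continue
                patch = sim_core.render_psf(
                    scene.coeffs,
                    float(np.clip(z_rel, -2, 2)),
                    scene.depth_um,
                    scene.cfg,
                    size_px=15,
                    shift_nm=(x - cx * px, y - cy * px),
                )
                sim_core._add_patch(photon_img, em.photons_mean * patch, cx, cy)
                visible.append((t, em.kind, x, y, z_rel))
        frames[t] = sim_core.apply_camera(photon_img, scene.camera, rng)
        truth_rows.extend(visible)

        # track the reference bead: fit a ROI around its expected position
        bx = bead.x_nm + shift[0]
        by = bead.y_nm + shift[1]
        cx, cy = int(round(bx / px)), int(round(by / px))
        loc = None
        if (
            half_roi <= cx < scene.img_shape[1] - half_roi
            and half_roi <= cy < scene.img_shape[0] - half_roi
        ):
            roi = frames[t].astype(float)[
                cy - half_roi : cy + half_roi + 1, cx - half_roi : cx + half_roi + 1
            ] - scene.camera.baseline_adu
            fit = fit_gaussian(roi, px, origin_px=(cy - half_roi, cx - half_roi))
            if fit.converged and fit.chi2 > 0.2:
                z_bead, _ = assign_z(fit.sigma_x_nm, fit.sigma_y_nm, cal)
                loc = (fit.x_nm, fit.y_nm, z_bead * 1000.0)
        corr = ctrl.step(t, loc)
        if corr is not None:
            pending.append((t + 1, np.asarray(corr)))
        if ctrl.aborted:
            frames = frames[: t + 1]
            break
    truth = pd.DataFrame(
        truth_rows, columns=["frame", "kind", "x_nm", "y_nm", "z_um"]
    )
    sh = np.stack(shifts)  # residual sample shift actually applied per frame
    stack = FrameStack(
        frames=frames,
        frame_rate_hz=10.0,
        plane_index=plane_index,
        ground_truth=truth,
        drift=DriftTrajectory(sh[:, 0], sh[:, 1], sh[:, 2]),
    )
    return stack, drift_now


def run_volume_acquisition(
    plan: AcquisitionPlan,
    scene: SimulatedScene,
    cal: AstigCalibration,
    seed: int = 0,
    *,
    window: int = 10,
) -> tuple[list[FrameStack], list[BeadTrack], list[int]]:
    """Sequential multi-plane acquisition with per-plane feedback correction.

    For each plane: a pre-acquisition fiducial image is localized,
    :func:`select_fiduciary` picks the reference bead, and
    ``frames_per_plane`` frames are acquired under closed-loop drift
    correction.  Planes without an eligible bead are skipped (logged as
    gaps).  Returns the per-plane stacks, bead tracks, and skipped plane
    indices; raises if every plane is bead-less.
    """
    rng = np.random.default_rng(seed)
    stacks: list[FrameStack] = []
    tracks: list[BeadTrack] = []
    gaps: list[int] = []
    drift_offset = np.zeros(3)
    for p in range(plan.n_planes):
        plane_z = plan.first_plane_z_um + p * plan.dz_nm / 1000.0
        plane_index = p + 1
        # pre-acquisition bead image: fiducials only, no blinking molecules
        beads_near = [
            b for b in scene.fiducials if abs(b.z_um - plane_z) <= scene.z_visible_um
        ]
        pre = sim_core.simulate_acquisition(
            [
                Emitter(
                    b.x_nm + drift_offset[0],
                    b.y_nm + drift_offset[1],
                    b.z_um - plane_z + drift_offset[2] / 1000.0,
                    b.photons_mean,
                    "fiducial",
                )
                for b in beads_near
            ],
            scene.kinetics,
            DriftTrajectory.zero(1),
            scene.coeffs,
            scene.camera,
            1,
            scene.cfg,
            int(rng.integers(1 << 31)),
            img_shape=scene.img_shape,
            depth_um=scene.depth_um,
            background_adu=scene.background_adu,
            plane_index=plane_index,
        )
        locs = localize_stack(
            pre, cal, scene.cfg.pixel_size_camera_nm, scene.camera.baseline_adu
        )
        # the tracking ROI must fit inside the frame: drop border beads
        px = scene.cfg.pixel_size_camera_nm
        margin = 8 * px
        if len(locs):
            inside = (
                locs["x_nm"].between(margin, scene.img_shape[1] * px - margin)
                & locs["y_nm"].between(margin, scene.img_shape[0] * px - margin)
            )
            locs = locs[inside].reset_index(drop=True)
        chosen = select_fiduciary(locs, plan.well_box_nm)
        if chosen is None:
            logger.warning("plane %d: no eligible fiduciary, skipping", plane_index)
            gaps.append(plane_index)
            continue
        # match the chosen localization back to a scene bead
        dists = [
            np.hypot(b.x_nm - chosen["x_nm"], b.y_nm - chosen["y_nm"])
            for b in beads_near
        ]
        bead = beads_near[int(np.argmin(dists))]
        reference = (chosen["x_nm"], chosen["y_nm"], chosen["z_um"] * 1000.0)
        ctrl = FeedbackController(
            reference,
            plan.drift_threshold_nm,
            window,
            plane_index=plane_index,
            bead_id=int(np.argmin(dists)),
        )
        stack, drift_offset = _acquire_plane(
            scene,
            plane_z,
            plane_index,
            plan.frames_per_plane,
            cal,
            ctrl,
            bead,
            drift_offset,
            rng,
        )
        stacks.append(stack)
        tracks.append(ctrl.track)
    if not stacks:
        raise RuntimeError("no plane had an eligible fiduciary")
    return stacks, tracks, gaps
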