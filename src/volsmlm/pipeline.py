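"""End-to-end pipeline on synthetic data.

simulation → adaptive-optics correction → astigmatism calibration →
multi-plane acquisition with feedback drift correction → localization →
offline drift correction + registration → volume assembly → rendering →
axial homogeneity and resolution reports.  Every stage's inputs and
outputs are persisted in the artifact directory together with a manifest.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .ao_3n import run_3n
from .io import PipelineConfig, save_config, write_localizations
from .localizer import calibrate_astigmatism, filter_localizations, localize_stack
from .sim_core import (
    BlinkKinetics,
    CameraModel,
    DriftTrajectory,
    Emitter,
    FrameStack,
    OpticalConfig,
    place_fiducials,
    render_psf,
    simulate_acquisition,
)
from .smartrack import AcquisitionPlan, SimulatedScene, run_volume_acquisition
from .volume_builder import (
    PlaneLocalizations,
    RenderConfig,
    assemble_volume,
    axial_cv,
    correct_residual_drift,
    remove_grid_artifact,
    render_volume,
)
from .zernike import ZernikeCoeffs

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "make_bead_zstack", "shell_molecules"]


def make_bead_zstack(
    coeffs: ZernikeCoeffs,
    cfg: OpticalConfig,
    camera: CameraModel,
    *,
    z_range_um: float = 0.6,
    z_step_um: float = 0.025,
    photons: float = 20000.0,
    depth_um: float = 0.0,
    seed: int = 0,
    noiseless: bool = True,
) -> tuple[FrameStack, float]:
    """Simulate the bead z-stack used for astigmatism calibration."""
    zs = np.arange(-z_range_um, z_range_um + z_step_um / 2, z_step_um)
    frames = []
    cam = CameraModel(
        baseline_adu=camera.baseline_adu,
        electrons_per_adu=camera.electrons_per_adu,
        quantum_efficiency=camera.quantum_efficiency,
        read_noise_e=0.0 if noiseless else camera.read_noise_e,
    )
    for i, z in enumerate(zs):
        st = simulate_acquisition(
            [Emitter(16 * cfg.pixel_size_camera_nm, 16 * cfg.pixel_size_camera_nm, z, photons, "fiducial")],
            BlinkKinetics(),
            DriftTrajectory.zero(1),
            coeffs,
            cam,
            1,
            cfg,
            seed + i,
            img_shape=(33, 33),
            depth_um=depth_um,
            shot_noise=not noiseless,
        )
        frames.append(st.frames[0])
    stack = FrameStack(
        np.asarray(frames), 10.0, 0, pd.DataFrame(), DriftTrajectory.zero(len(zs))
    )
    return stack, z_step_um


def shell_molecules(
    n: int,
    center_nm: tuple[float, float],
    radius_nm: float,
    z_range_um: tuple[float, float],
    photons: float,
    seed: int,
) -> list[Emitter]:
    """Docking sites on a vertical cylindrical shell (nuclear-envelope-like)."""
    rng = np.random.default_rng(seed)
    ang = rng.uniform(0, 2 * np.pi, n)
    z = rng.uniform(z_range_um[0], z_range_um[1], n)
    return [
        Emitter(
            center_nm[0] + radius_nm * np.cos(a),
            center_nm[1] + radius_nm * np.sin(a),
            float(zz),
            photons,
            "molecule",
        )
        for a, zz in zip(ang, z)
    ]


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run the whole synthetic pipeline; returns the manifest dict.

    Deterministic for a fixed ``config.seed``.  Artifacts written: config,
    correction log (JSON), calibration curve (CSV), per-plane TIFF stacks
    and localization CSVs, bead tracks, merged volume CSV, rendered stack
    (32-bit TIFF), and a JSON report of the axial CV and stage summary.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    save_config(config, out / "config.yaml")
    seed = config.seed
    cfg = OpticalConfig(
        numerical_aperture=config.optics.numerical_aperture,
        wavelength_nm=config.optics.wavelength_nm,
        pixel_size_camera_nm=config.optics.pixel_size_camera_nm,
        pupil_grid_size=config.optics.pupil_grid_size,
        depth_spherical_slope_rad_per_um=config.optics.depth_spherical_slope_rad_per_um,
    )
    camera = CameraModel(
        baseline_adu=config.camera.baseline_adu,
        electrons_per_adu=config.camera.electrons_per_adu,
        quantum_efficiency=config.camera.quantum_efficiency,
        read_noise_e=config.camera.read_noise_e,
    )
    kinetics = BlinkKinetics(
        on_rate_per_frame=config.kinetics.on_rate_per_frame,
        mean_on_frames=config.kinetics.mean_on_frames,
    )
    rng = np.random.default_rng(seed)

    # stage 1: sensorless AO on a simulated bead at depth
    depth_um = 10.0
    intrinsic = ZernikeCoeffs({"coma_horizontal": 30.0, "astig_oblique": 20.0})

    def system(correction: ZernikeCoeffs) -> np.ndarray:
        return render_psf(intrinsic.add(correction), 0.0, depth_um, cfg, size_px=21)

    ao_state = run_3n(
        system,
        modes=tuple(config.ao.modes),
        alpha_nm=config.ao.alpha_nm,
        iterations=config.ao.iterations,
    )
    (out / "ao_correction.json").write_text(
        json.dumps(
            {
                "correction_nm": ao_state.correction.coefficients,
                "initial_merit": ao_state.initial_merit,
                "final_merit": ao_state.final_merit,
                "evaluations": [
                    {
                        "mode": e.mode,
                        "coeffs": e.sampled_coeffs,
                        "merits": e.merits,
                        "alpha_opt_nm": e.alpha_opt_nm,
                    }
                    for e in ao_state.log
                ],
            },
            indent=1,
        )
    )
    residual = intrinsic.add(ao_state.correction)

    # stage 2: induce astigmatism and calibrate sigma(z)
    astig = config.optics.astigmatism_nm
    imaging_coeffs = residual.with_mode(
        "astig_vertical", residual.get("astig_vertical") + astig
    )
    zstack, z_step = make_bead_zstack(imaging_coeffs, cfg, camera, depth_um=depth_um, seed=seed)
    cal = calibrate_astigmatism(zstack, z_step, cfg.pixel_size_camera_nm)
    pd.DataFrame(
        {"z_um": cal.z_um, "sigma_x_nm": cal.sigma_x_nm, "sigma_y_nm": cal.sigma_y_nm}
    ).to_csv(out / "calibration.csv", index=False)

    # stage 3: build the scene and acquire all planes under feedback
    px = cfg.pixel_size_camera_nm
    fov_nm = 48 * px
    n_planes = config.plan.n_planes
    z_top = config.plan.first_plane_z_um + (n_planes - 1) * config.plan.dz_nm / 1000.0
    molecules = shell_molecules(
        300,
        (fov_nm / 2, fov_nm / 2),
        fov_nm / 4,
        (config.plan.first_plane_z_um - 0.3, z_top + 0.3),
        camera.photons_for_signal_adu(3500.0),
        seed + 1,
    )
    volume_um = (fov_nm / 1000.0, fov_nm / 1000.0, z_top - config.plan.first_plane_z_um + 1.0)
    beads = place_fiducials(0.3, volume_um, seed=seed + 2, photons_mean=8000.0)
    beads = [
        Emitter(b.x_nm, b.y_nm, b.z_um + config.plan.first_plane_z_um - 0.5, b.photons_mean, "fiducial")
        for b in beads
    ]
    scene = SimulatedScene(
        molecules=molecules,
        fiducials=beads,
        kinetics=kinetics,
        coeffs=imaging_coeffs,
        camera=camera,
        cfg=cfg,
        img_shape=(48, 48),
        depth_um=depth_um,
        background_adu=20.0,
        drift_rate_nm_per_frame=(0.15, -0.1, 0.1),
    )
    plan = AcquisitionPlan(
        first_plane_z_um=config.plan.first_plane_z_um,
        n_planes=n_planes,
        dz_nm=config.plan.dz_nm,
        frames_per_plane=config.plan.frames_per_plane,
        drift_threshold_nm=config.plan.drift_threshold_nm,
    )
    stacks, tracks, gaps = run_volume_acquisition(
        plan, scene, cal, seed + 3, window=config.plan.averaging_window
    )

    # stage 4: localize, correct residual drift, assemble
    planes = []
    for stack, track in zip(stacks, tracks):
        tifffile.imwrite(out / f"plane_{stack.plane_index:02d}.tif", stack.frames)
        locs = localize_stack(
            stack,
            cal,
            px,
            camera.baseline_adu,
            config.localization.threshold_factor,
            roi_px=config.localization.roi_px,
        )
        locs["plane_index"] = stack.plane_index
        # split off fiducial localizations (near a known bead, persistent)
        is_fid = np.zeros(len(locs), dtype=bool)
        for b in scene.fiducials:
            d = np.hypot(locs["x_nm"] - b.x_nm, locs["y_nm"] - b.y_nm)
            is_fid |= (d < 3 * px).to_numpy()
        fid_locs = locs[is_fid].reset_index(drop=True)
        bead_ids = np.full(len(fid_locs), -1)
        for k, b in enumerate(scene.fiducials):
            d = np.hypot(fid_locs["x_nm"] - b.x_nm, fid_locs["y_nm"] - b.y_nm)
            bead_ids[(d < 3 * px).to_numpy()] = k
        fid_locs["bead_id"] = bead_ids
        mol_locs = filter_localizations(
            locs[~is_fid].reset_index(drop=True),
            config.localization.chi2_min,
            config.localization.chi2_max,
            -config.localization.z_range_um,
            config.localization.z_range_um,
        )
        plane = PlaneLocalizations(
            plane_index=stack.plane_index,
            localizations=mol_locs,
            bead_track=track,
            fiducial_localizations=fid_locs,
        )
        plane = correct_residual_drift(plane, config.plan.averaging_window)
        write_localizations(
            plane.localizations, out / f"locs_plane_{stack.plane_index:02d}.csv"
        )
        track.to_frame().to_csv(
            out / f"beadtrack_plane_{stack.plane_index:02d}.csv", index=False
        )
        planes.append(plane)

    volume = assemble_volume(planes, config.plan.dz_nm)
    write_localizations(volume, out / "volume.csv")

    render_cfg = RenderConfig(
        sr_pixel_nm=config.render.sr_pixel_nm,
        plane_spacing_nm=config.render.plane_spacing_nm,
        blur_lateral_nm=config.render.blur_lateral_nm,
        blur_axial_nm=config.render.blur_axial_nm,
        camera_pixel_nm=px,
    )
    stack3d, origin = render_volume(volume, render_cfg)
    if config.render.grid_filter:
        stack3d = np.stack(
            [remove_grid_artifact(plane, px, render_cfg.zoom) for plane in stack3d]
        ).astype(np.float32)
    tifffile.imwrite(out / "render.tif", stack3d.astype(np.float32))

    z_span = volume["z_nm"].max() - volume["z_nm"].min() if len(volume) else 0.0
    cv = axial_cv(volume, config.plan.dz_nm) if z_span > config.plan.dz_nm else float("nan")
    manifest = {
        "version": __version__,
        "seed": seed,
        "n_planes_acquired": len(stacks),
        "skipped_planes": gaps,
        "n_localizations": int(len(volume)),
        "axial_cv": None if np.isnan(cv) else float(cv),
        "ao_initial_merit": ao_state.initial_merit,
        "ao_final_merit": ao_state.final_merit,
        "calibration_symmetry": cal.symmetry_score,
        "parameters": config.to_dict(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
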