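"""Detection, Gaussian fitting, astigmatic calibration and z assignment."""

import numpy as np
import pandas as pd
import pytest

from volsmlm.localizer import (
    assign_z,
    calibrate_astigmatism,
    detect_spots,
    filter_localizations,
    fit_gaussian,
    localize_stack,
)
from volsmlm.pipeline import make_bead_zstack
from volsmlm.sim_core import (
    BlinkKinetics,
    CameraModel,
    DriftTrajectory,
    Emitter,
    simulate_acquisition,
)
from volsmlm.zernike import ZernikeCoeffs

ALWAYS_ON = BlinkKinetics(on_rate_per_frame=100.0, mean_on_frames=1e9)


def simulate_single(cfg, camera, coeffs, x_nm, y_nm, z_um, photons, seed, **kw):
    return simulate_acquisition(
        [Emitter(x_nm, y_nm, z_um, photons, "molecule")],
        ALWAYS_ON, DriftTrajectory.zero(1), coeffs, camera, 1, cfg, seed,
        img_shape=kw.pop("img_shape", (33, 33)), **kw,
    )


class TestDetect:
    def test_flat_frame_no_candidates(self):
        assert detect_spots(np.zeros((32, 32))) == []

    def test_single_psf_one_candidate(self, cfg, camera_noiseless, astig60):
        stack = simulate_single(
            cfg, camera_noiseless, astig60, 16 * 108.0, 15 * 108.0, 0.0,
            camera_noiseless.photons_for_signal_adu(3500.0), seed=0, shot_noise=False,
        )
        cands = detect_spots(stack.frames[0].astype(float) - 100.0)
        assert len(cands) == 1
        cy, cx = cands[0]
        assert abs(cx - 16) <= 1 and abs(cy - 15) <= 1

    def test_two_separated_psfs_two_candidates(self, cfg, camera_noiseless, astig60):
        ems = [
            Emitter(8 * 108.0, 16 * 108.0, 0.0, 3000.0),
            Emitter(28 * 108.0, 16 * 108.0, 0.0, 3000.0),
        ]
        stack = simulate_acquisition(
            ems, ALWAYS_ON, DriftTrajectory.zero(1), astig60, camera_noiseless,
            1, cfg, 0, img_shape=(33, 37), shot_noise=False,
        )
        assert len(detect_spots(stack.frames[0].astype(float) - 100.0)) == 2


class TestFitGaussian:
    def test_noiseless_recovery(self):
        """Rendered Gaussian (150/200 nm): parameters back to < 0.5 nm."""
        yg, xg = np.mgrid[0:15, 0:15].astype(float)
        sx, sy = 150.0 / 108, 200.0 / 108
        model = 900 * np.exp(
            -((xg - 7.2) ** 2) / (2 * sx**2) - ((yg - 7.6) ** 2) / (2 * sy**2)
        ) + 12.0
        fit = fit_gaussian(model, 108.0)
        assert abs(fit.x_nm - 7.2 * 108) < 0.5
        assert abs(fit.y_nm - 7.6 * 108) < 0.5
        assert abs(fit.sigma_x_nm - 150.0) < 0.5
        assert abs(fit.sigma_y_nm - 200.0) < 0.5
        assert fit.chi2 > 0.999

    def test_pure_noise_low_chi2(self, rng):
        fit = fit_gaussian(rng.normal(0, 5, (15, 15)), 108.0)
        assert fit.chi2 < 0.6  # later removed by the quality filter

    def test_isotropic_input_fits_isotropic(self, cfg, camera_noiseless):
        stack = simulate_single(
            cfg, camera_noiseless, ZernikeCoeffs(), 16 * 108.0, 16 * 108.0, 0.0,
            2e4, seed=0, shot_noise=False,
        )
        roi = stack.frames[0].astype(float)[9:24, 9:24] - 100.0
        fit = fit_gaussian(roi, 108.0, origin_px=(9, 9))
        assert abs(fit.sigma_x_nm - fit.sigma_y_nm) < 2.0

    def test_small_roi_rejected(self):
        with pytest.raises(ValueError):
            fit_gaussian(np.zeros((5, 5)), 108.0)


class TestCalibration:
    def test_focus_at_stack_center(self, calibration):
        """Symmetric astigmatic stack: z* within one step of the center."""
        assert abs(calibration.z_um[len(calibration.z_um) // 2]) <= 0.025 + 1e-9
        sx0, sy0 = calibration.sigmas_at(0.0)
        assert sx0 == pytest.approx(sy0, rel=0.01)

    def test_symmetry_degrades_with_spherical(self, cfg, camera, calibration, astig60):
        stack, z_step = make_bead_zstack(
            astig60.with_mode("spherical", 25.0), cfg, camera
        )
        cal_aberrated = calibrate_astigmatism(stack, z_step, cfg.pixel_size_camera_nm)
        assert cal_aberrated.symmetry_score > calibration.symmetry_score

    def test_fine_step_protocol_accepted(self, calibration):
        # the session calibration uses a 25 nm step over +-0.6 um
        assert len(calibration.z_um) >= 40

    def test_too_coarse_step_rejected(self, cfg, camera, astig60):
        stack, _ = make_bead_zstack(astig60, cfg, camera, z_step_um=0.1)
        with pytest.raises(ValueError):
            calibrate_astigmatism(stack, 0.1, cfg.pixel_size_camera_nm)

    def test_no_astigmatism_rejected(self, cfg, camera):
        """Without astigmatism sigma_x - sigma_y never crosses: unusable."""
        stack, z_step = make_bead_zstack(ZernikeCoeffs(), cfg, camera)
        with pytest.raises(ValueError):
            calibrate_astigmatism(stack, z_step, cfg.pixel_size_camera_nm)


class TestAssignZ:
    def test_equal_sigmas_map_to_focus(self, calibration):
        sx0, _ = calibration.sigmas_at(0.0)
        z, out = assign_z(float(sx0), float(sx0), calibration)
        assert abs(z) <= 0.005 and not out

    def test_lookup_identity(self, calibration):
        sx, sy = calibration.sigmas_at(0.3)
        z, out = assign_z(float(sx), float(sy), calibration)
        assert z == pytest.approx(0.300, abs=0.002)
        assert not out

    def test_boundary_flagged_out_of_range(self, calibration):
        sx, sy = calibration.sigmas_at(0.55)
        _, out = assign_z(float(sx), float(sy), calibration, z_max_um=0.5)
        assert out

    def test_z_rmse_under_60nm(self, cfg, camera, astig60, calibration):
        """Emitters uniform in z (+-0.4 um) at 3500 ADU: z RMSE < 60 nm."""
        rng = np.random.default_rng(2)
        photons = camera.photons_for_signal_adu(3500.0)
        errors = []
        for _ in range(40):
            z = rng.uniform(-0.4, 0.4)
            x = rng.uniform(12, 20) * 108.0
            y = rng.uniform(12, 20) * 108.0
            stack = simulate_single(
                cfg, camera, astig60, x, y, z, photons,
                seed=int(rng.integers(1 << 31)), background_adu=20.0,
            )
            locs = localize_stack(stack, calibration, 108.0, 100.0)
            if len(locs) == 0:
                continue
            d = np.hypot(locs["x_nm"] - x, locs["y_nm"] - y)
            if d.min() > 250:
                continue
            errors.append(locs["z_um"].iloc[int(np.argmin(d.values))] - z)
        assert len(errors) > 30
        assert 1000 * np.sqrt(np.mean(np.square(errors))) < 60.0


class TestFilters:
    @pytest.mark.parametrize(
        "chi2,z,kept",
        [(0.7, 0.3, True), (0.5, 0.0, False), (0.9, 0.6, False),
         (0.6, -0.5, True), (1.0, 0.5, True)],
    )
    def test_quality_filter_bounds(self, chi2, z, kept):
        locs = pd.DataFrame({"chi2": [chi2], "z_um": [z]})
        assert len(filter_localizations(locs)) == (1 if kept else 0)


class TestPrecision:
    def test_precision_scales_inverse_sqrt_photons(self, cfg, camera, astig60, calibration):
        """Lateral precision ~ N^-1/2: log-log slope -0.5 +- 0.1."""
        rng = np.random.default_rng(3)
        levels = [800.0, 3200.0, 12800.0]
        precisions = []
        for photons in levels:
            errs = []
            for _ in range(30):
                x = rng.uniform(14, 18) * 108.0
                y = rng.uniform(14, 18) * 108.0
                stack = simulate_single(
                    cfg, camera, astig60, x, y, 0.0, photons,
                    seed=int(rng.integers(1 << 31)), background_adu=10.0,
                )
                locs = localize_stack(stack, calibration, 108.0, 100.0)
                if len(locs) == 0:
                    continue
                d = np.hypot(locs["x_nm"] - x, locs["y_nm"] - y)
                if d.min() < 250:
                    errs.append(d.min())
            precisions.append(np.sqrt(np.mean(np.square(errs))) / np.sqrt(2))
        slope = np.polyfit(np.log(levels), np.log(precisions), 1)[0]
        assert slope == pytest.approx(-0.5, abs=0.1)

    def test_in_focus_localization_unbiased(self, cfg, camera, astig60, calibration):
        """Mean lateral error < 2 nm over many in-focus emitters."""
        rng = np.random.default_rng(4)
        ex, ey = [], []
        for _ in range(60):
            x = rng.uniform(14, 18) * 108.0
            y = rng.uniform(14, 18) * 108.0
            stack = simulate_single(
                cfg, camera, astig60, x, y, 0.0, 8000.0,
                seed=int(rng.integers(1 << 31)),
            )
            locs = localize_stack(stack, calibration, 108.0, 100.0)
            if len(locs) == 0:
                continue
            d = np.hypot(locs["x_nm"] - x, locs["y_nm"] - y)
            i = int(np.argmin(d.values))
            if d.min() < 250:
                ex.append(locs["x_nm"].iloc[i] - x)
                ey.append(locs["y_nm"].iloc[i] - y)
        assert len(ex) > 50
        assert abs(np.mean(ex)) < 2.0 and abs(np.mean(ey)) < 2.0

    def test_yield_drops_beyond_400nm(self, cfg, camera, astig60, calibration):
        """Detection/fit yield at |z| = 0.45 um below the in-focus yield.

        Probed at the upper end of the DNA-PAINT background range, where
        the dilution of defocused PSFs into the background is limiting.
        """
        rng = np.random.default_rng(5)
        photons = camera.photons_for_signal_adu(3500.0)

        def yield_at(z):
            n_found = 0
            for _ in range(25):
                x = rng.uniform(14, 18) * 108.0
                y = rng.uniform(14, 18) * 108.0
                stack = simulate_single(
                    cfg, camera, astig60, x, y, z, photons,
                    seed=int(rng.integers(1 << 31)), background_adu=150.0,
                )
                locs = localize_stack(stack, calibration, 108.0, 100.0, apply_filters=True)
                if len(locs) and np.hypot(locs["x_nm"] - x, locs["y_nm"] - y).min() < 250:
                    n_found += 1
            return n_found / 25

        assert yield_at(0.45) < yield_at(0.0)
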