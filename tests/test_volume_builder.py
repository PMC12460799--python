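"""Residual drift correction, plane registration, assembly, rendering."""

import numpy as np
import pandas as pd
import pytest

from volsmlm.smartrack import BeadTrack
from volsmlm.volume_builder import (
    PlaneLocalizations,
    RenderConfig,
    assemble_volume,
    axial_cv,
    correct_residual_drift,
    register_planes,
    remove_grid_artifact,
    render_volume,
)


def make_track(frames, disp, plane_index=1, window=10):
    """BeadTrack with given per-frame displacement array (n, 3)."""
    track = BeadTrack(
        bead_id=0, reference_nm=(0.0, 0.0, 0.0), plane_index=plane_index,
        averaging_window=window,
    )
    track.frames = list(frames)
    track.positions_nm = [tuple(d) for d in disp]
    track.drifts_nm = [float(np.linalg.norm(d)) for d in disp]
    return track


def make_locs(x, y, z_um, frames, plane_index=1):
    return pd.DataFrame(
        {
            "loc_id": np.arange(len(x)),
            "frame": frames,
            "x_nm": x, "y_nm": y, "z_um": z_um,
            "plane_index": plane_index,
        }
    )


class TestResidualDrift:
    def test_constant_trajectory_is_identity(self):
        """A static bead means no residual drift: localizations untouched."""
        disp = np.tile([5.0, -3.0, 2.0], (50, 1))
        track = make_track(range(50), disp)
        locs = make_locs([100.0, 200.0], [50.0, 60.0], [0.1, 0.2], [10, 40])
        plane = PlaneLocalizations(1, locs, track)
        out = correct_residual_drift(plane)
        pd.testing.assert_series_equal(out.localizations["x_nm"], locs["x_nm"])

    def test_linear_residual_reduced(self):
        """20 nm linear residual: a static emitter tightens >= 4x."""
        n = 200
        resid = np.linspace(0, 20.0, n)
        disp = np.stack([resid, np.zeros(n), np.zeros(n)], axis=1)
        track = make_track(range(n), disp)
        # static emitter observed at the drifted positions
        locs = make_locs(1000.0 + resid, np.full(n, 500.0), np.zeros(n), range(n))
        out = correct_residual_drift(PlaneLocalizations(1, locs, track))
        rms_before = np.std(locs["x_nm"])
        rms_after = np.std(out.localizations["x_nm"])
        assert rms_before / rms_after >= 4.0

    def test_bead_trajectory_variance_decreases(self):
        rng = np.random.default_rng(0)
        n = 300
        resid = np.cumsum(rng.normal(0, 1.0, n))
        disp = np.stack([resid, resid * 0.5, np.zeros(n)], axis=1)
        track = make_track(range(n), disp)
        bead_locs = make_locs(disp[:, 0], disp[:, 1], np.zeros(n), range(n))
        out = correct_residual_drift(
            PlaneLocalizations(1, bead_locs, track)
        )
        assert np.var(out.localizations["x_nm"]) < np.var(bead_locs["x_nm"])

    def test_missing_track_passthrough(self):
        locs = make_locs([1.0], [2.0], [0.0], [0])
        out = correct_residual_drift(PlaneLocalizations(1, locs, None))
        assert out.localizations is locs


class TestRegistration:
    def test_identical_beads_zero_shift(self):
        beads = pd.DataFrame({"x_nm": [0.0, 1000.0, 2000.0], "y_nm": [0.0, 500.0, 800.0]})
        assert register_planes(beads, beads) == pytest.approx((0.0, 0.0))

    def test_uniform_offset_recovered_exactly(self):
        beads = pd.DataFrame({"x_nm": [0.0, 1000.0, 2000.0, 1500.0],
                              "y_nm": [0.0, 500.0, 800.0, 1200.0]})
        shifted = beads.copy()
        shifted["x_nm"] -= 12.0
        shifted["y_nm"] += 7.0
        dx, dy = register_planes(beads, shifted)
        assert (dx, dy) == pytest.approx((12.0, -7.0))

    def test_noise_scaling_sigma_over_sqrt_n(self):
        """Per-bead noise sigma, n=8 beads: shift RMS error ~ sigma/sqrt(8)."""
        rng = np.random.default_rng(1)
        sigma, n_beads = 6.0, 8
        errors = []
        for _ in range(100):
            beads = pd.DataFrame({
                "x_nm": rng.uniform(0, 20000, n_beads),
                "y_nm": rng.uniform(0, 20000, n_beads),
            })
            noisy = beads.copy()
            noisy["x_nm"] += rng.normal(0, sigma, n_beads)
            noisy["y_nm"] += rng.normal(0, sigma, n_beads)
            dx, dy = register_planes(beads, noisy)
            errors.extend([dx, dy])
        rms = float(np.sqrt(np.mean(np.square(errors))))
        expected = sigma / np.sqrt(n_beads)  # noise in the second plane only
        assert rms == pytest.approx(expected, rel=0.25)

    def test_too_few_shared_beads_raises(self):
        a = pd.DataFrame({"x_nm": [0.0, 10000.0], "y_nm": [0.0, 0.0]})
        b = pd.DataFrame({"x_nm": [0.0, 30000.0], "y_nm": [0.0, 0.0]})
        with pytest.raises(ValueError):
            register_planes(a, b)  # only one bead matches within 500 nm


class TestAssembly:
    def _plane(self, index, z_um, fid_xy=None):
        locs = make_locs([1000.0], [1000.0], [z_um], [0], plane_index=index)
        fid = None
        if fid_xy is not None:
            fid = pd.DataFrame({
                "bead_id": np.arange(len(fid_xy)),
                "x_nm": [p[0] for p in fid_xy],
                "y_nm": [p[1] for p in fid_xy],
                "frame": 0,
            })
        return PlaneLocalizations(index, locs, None, fid)

    def test_vertical_offsets(self):
        """z_total = z*1000 + (i-1)*dz: plane 1 offset 0, plane 5 at 1400."""
        planes = [self._plane(1, 0.1), self._plane(5, -0.2)]
        vol = assemble_volume(planes, 350.0, register=False)
        assert vol.loc[vol.plane_index == 1, "z_nm"].iloc[0] == pytest.approx(100.0)
        assert vol.loc[vol.plane_index == 5, "z_nm"].iloc[0] == pytest.approx(-200.0 + 4 * 350.0)

    def test_loc_ids_unique_sequential(self):
        planes = [self._plane(1, 0.0), self._plane(2, 0.0)]
        vol = assemble_volume(planes, 350.0, register=False)
        assert list(vol["loc_id"]) == list(range(len(vol)))

    def test_registration_applied_cumulatively(self):
        fid = [(5000.0, 5000.0), (9000.0, 2000.0), (2000.0, 8000.0)]
        p1 = self._plane(1, 0.0, fid)
        shifted = [(x - 15.0, y + 9.0) for x, y in fid]
        p2 = self._plane(2, 0.0, shifted)
        p2.localizations["x_nm"] -= 15.0
        p2.localizations["y_nm"] += 9.0
        vol = assemble_volume([p1, p2], 350.0)
        xs = vol.groupby("plane_index")["x_nm"].first()
        assert xs[2] == pytest.approx(xs[1], abs=1e-9)

    def test_equivariance_under_global_translation(self):
        fid = [(5000.0, 5000.0), (9000.0, 2000.0), (2000.0, 8000.0)]
        planes = [self._plane(1, 0.0, fid), self._plane(2, 0.1, fid)]
        vol = assemble_volume(planes, 350.0)
        moved = []
        for p in [self._plane(1, 0.0, fid), self._plane(2, 0.1, fid)]:
            p.localizations[["x_nm", "y_nm"]] += 777.0
            p.fiducial_localizations[["x_nm", "y_nm"]] += 777.0
            moved.append(p)
        vol2 = assemble_volume(moved, 350.0)
        assert np.allclose(vol2["x_nm"], vol["x_nm"] + 777.0)
        assert np.allclose(vol2["z_nm"], vol["z_nm"])


class TestAxialCv:
    def test_equal_counts_zero_cv(self):
        z = np.repeat([100.0, 300.0, 500.0], 50)
        vol = pd.DataFrame({"z_nm": z})
        assert axial_cv(vol, 200.0) == pytest.approx(0.0)

    def test_two_bin_example(self):
        """Counts (100, 300): population std/mean = 0.5."""
        z = np.concatenate([np.full(100, 50.0), np.full(300, 250.0)])
        vol = pd.DataFrame({"z_nm": z})
        assert axial_cv(vol, 200.0) == pytest.approx(0.5)

    def test_empty_volume_raises(self):
        with pytest.raises(ValueError):
            axial_cv(pd.DataFrame({"z_nm": []}))


class TestRender:
    def test_single_localization_blob_fwhm(self):
        vol = pd.DataFrame({"x_nm": [500.0], "y_nm": [500.0], "z_nm": [0.0]})
        stack, origin = render_volume(vol, RenderConfig())
        iz, iy, ix = np.unravel_index(np.argmax(stack), stack.shape)
        prof = stack[iz, iy, :].astype(float)
        half = prof >= prof.max() / 2
        fwhm = half.sum() * 10.0
        assert fwhm == pytest.approx(23.5, abs=10.0)  # 2.355 sigma on a 10 nm grid
        # blob centered at the localization
        assert abs(origin[0] + ix * 10.0 - 500.0) <= 5.0

    def test_intensity_linear_in_count(self):
        one = pd.DataFrame({"x_nm": [300.0], "y_nm": [300.0], "z_nm": [0.0]})
        two = pd.concat([one, one], ignore_index=True)
        cfg = RenderConfig()
        s1, _ = render_volume(one, cfg)
        s2, _ = render_volume(two, cfg)
        assert s2.sum() == pytest.approx(2 * s1.sum(), rel=1e-6)

    def test_empty_volume_zero_stack(self):
        stack, _ = render_volume(pd.DataFrame({"x_nm": [], "y_nm": [], "z_nm": []}), RenderConfig())
        assert stack.sum() == 0


class TestGridFilter:
    def test_grid_period_removed(self):
        """Cosine grid at the camera-pixel period is fully suppressed."""
        zoom = 10.8
        n = 270
        x = np.arange(n)
        grid = np.cos(2 * np.pi * x / zoom)
        img = 50.0 + 5.0 * (grid[None, :] + grid[:, None])
        out = remove_grid_artifact(img, 108.0, zoom)
        grid_power_in = np.sum((img - img.mean()) ** 2)
        grid_power_out = np.sum((out - out.mean()) ** 2)
        assert grid_power_out < 1e-6 * grid_power_in
        assert out.mean() == pytest.approx(img.mean(), rel=1e-12)  # DC preserved

    def test_transparent_off_target(self, rng):
        """An image with no energy in the filtered bins passes unchanged."""
        n, zoom = 200, 10.0
        img = rng.normal(100, 10, (n, n))
        pre = remove_grid_artifact(img, 108.0, zoom)  # strips the target bins
        out = remove_grid_artifact(pre, 108.0, zoom)
        assert np.max(np.abs(out - pre)) < 1e-10 * np.max(np.abs(pre))

    def test_small_image_rejected(self):
        with pytest.raises(ValueError):
            remove_grid_artifact(np.ones((4, 4)), 108.0, 10.0)
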