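"""Synthetic Slimfield generator: rendering physics and ground truth."""

import numpy as np
import pytest

from slimspore.simulate import (CellGeometry, EmitterModel, NoiseModel,
                                apply_noise, build_cell_model, render_frame,
                                render_spots, simulate_bleach_stack,
                                simulate_diffusing_foci, simulate_frap,
                                bleach_traces)


class TestCellModel:
    def test_stage_I_has_membrane_only_in_fm_channel(self):
        geom = CellGeometry(stage="I")
        fm = build_cell_model(geom, seed=0, channel="FM")
        my = build_cell_model(geom, seed=0, channel="mYPet")
        assert fm.n > 0
        assert my.n == 0

    def test_stage_II_i_feature_is_cell_width_disk_near_pole(self):
        geom = CellGeometry(stage="II_i")
        my = build_cell_model(geom, seed=0, channel="mYPet")
        pos = my.positions_nm
        # a disk perpendicular to the axis: tiny axial spread (wall jitter
        # only), transverse radius up to the cell radius
        assert pos[:, 0].std() < geom.wall_nm
        r_trans = np.hypot(pos[:, 1], pos[:, 2]).max()
        assert r_trans == pytest.approx(geom.radius_nm, rel=0.15)
        # near the pole-side end of the cell
        assert pos[:, 0].mean() > geom.length_nm / 2

    def test_unknown_stage_rejected(self):
        with pytest.raises(ValueError, match="stage"):
            CellGeometry(stage="IV")

    def test_membrane_positions_lie_on_declared_surfaces(self):
        geom = CellGeometry(stage="I")
        fm = build_cell_model(geom, seed=1, channel="FM")
        pos = fm.positions_nm
        body = (pos[:, 0] >= 0) & (pos[:, 0] <= geom.length_nm)
        r_cyl = np.hypot(pos[body, 1], pos[body, 2])
        # within the 1-px wall (radial jitter is +-wall/2 per axis)
        assert np.all(np.abs(r_cyl - geom.radius_nm) <= geom.wall_nm)

    def test_zero_length_limit_degenerates_to_caps_only(self):
        geom = CellGeometry(length_um=1e-6, stage="I")
        fm = build_cell_model(geom, seed=0, channel="FM")
        r = np.linalg.norm(fm.positions_nm
                           - np.array([geom.length_nm / 2, 0, 0]), axis=1)
        # all emitters on a spherical shell (two caps, no cylinder area)
        assert np.all(np.abs(r - geom.radius_nm) <= 1.5 * geom.wall_nm)


class TestRendering:
    def test_empty_model_renders_zero_frame(self):
        geom = CellGeometry(stage="I")
        model = EmitterModel(np.empty((0, 3)), np.empty(0), "mYPet", geom)
        frame = render_frame(model, noise=None)
        assert np.all(frame == 0)

    def test_single_in_focus_emitter_fwhm_matches_psf(self):
        frame = render_spots((41, 41), np.array([20.0]), np.array([20.0]),
                             np.array([250 / 2.355 / 80]), np.array([1000.0]))
        profile = frame[20]
        half = profile.max() / 2
        above = np.where(profile >= half)[0]
        fwhm_px = above[-1] - above[0] + 1
        assert fwhm_px * 80 == pytest.approx(250, abs=80)
        # second-moment width is a sharper check
        x = np.arange(41)
        mu = (profile * x).sum() / profile.sum()
        sd = np.sqrt((profile * (x - mu) ** 2).sum() / profile.sum())
        assert sd * 2.355 * 80 == pytest.approx(250, rel=0.05)

    def test_photon_conservation(self):
        rng = np.random.default_rng(0)
        n = 50
        frame = render_spots((64, 64), rng.uniform(20, 44, n),
                             rng.uniform(20, 44, n),
                             rng.uniform(1.0, 3.0, n), np.full(n, 77.0))
        assert frame.sum() == pytest.approx(n * 77.0, rel=0.01)

    def test_defocused_emitter_is_wider_but_conserves_photons(self):
        geom = CellGeometry(stage="I")
        sharp = EmitterModel(np.array([[1200.0, 0, 0]]), np.array([500.0]),
                             "mYPet", geom)
        blurred = EmitterModel(np.array([[1200.0, 0, 450.0]]),
                               np.array([500.0]), "mYPet", geom)
        f1 = render_frame(sharp, noise=None)
        f2 = render_frame(blurred, noise=None)
        assert f2.max() < f1.max()
        assert f2.sum() == pytest.approx(f1.sum(), rel=0.01)

    def test_poisson_noise_preserves_expectation(self):
        expected = np.full((5, 5), 40.0)
        noise = NoiseModel(background_offset=10.0, poisson=True)
        draws = np.stack([
            apply_noise(expected, noise, np.random.default_rng(s))
            for s in range(1000)
        ])
        mean = draws.mean(axis=0)
        se = draws.std(axis=0) / np.sqrt(len(draws))
        # 4 SE per pixel guards the 25-pixel multiplicity
        assert np.all(np.abs(mean - 50.0) < 4 * se + 1e-9)
        assert mean.mean() == pytest.approx(50.0, abs=3 * se.mean() / 5)

    def test_render_is_reproducible_given_seed(self):
        geom = CellGeometry(stage="II_i")
        model = build_cell_model(geom, seed=5, channel="FM")
        noise = NoiseModel.from_preset("average")
        f1 = render_frame(model, noise=noise, seed=9)
        f2 = render_frame(model, noise=noise, seed=9)
        np.testing.assert_array_equal(f1, f2)


class TestBleachStack:
    def test_single_molecule_single_step_to_zero(self):
        stack, truth = simulate_bleach_stack([((10.0, 10.0), 1)], t_b_ms=50,
                                             I_single=100, n_frames=40,
                                             noise=None, seed=2, shape=(24, 24))
        trace = bleach_traces(stack, truth)[0]
        levels = np.unique(np.round(trace / 100))
        assert set(levels.astype(int)) <= {0, 1}
        # exactly one downward transition
        steps = np.diff((trace > 50).astype(int))
        assert np.sum(steps == -1) == 1

    def test_infinite_bleach_time_gives_constant_traces(self):
        stack, truth = simulate_bleach_stack([((10.0, 10.0), 3)], t_b_ms=1e12,
                                             I_single=100, n_frames=20,
                                             noise=None, seed=0, shape=(24, 24))
        trace = bleach_traces(stack, truth)[0]
        assert trace.std() < 1e-6 * trace.mean()

    def test_ensemble_decay_recovers_bleach_time(self):
        t_b = 100.0
        traces = []
        for seed in range(6):
            stack, truth = simulate_bleach_stack(
                [((8 + 12 * (k % 3), 8 + 12 * (k // 3)), 4) for k in range(9)],
                t_b_ms=t_b, I_single=100, n_frames=100, noise=None,
                seed=seed, shape=(44, 44))
            traces.append(truth.extras["surviving"].sum(axis=0))
        mean = np.mean(traces, axis=0).astype(float)
        t = np.arange(100) * 5.0
        keep = mean > 0.02 * mean[0]
        slope = np.polyfit(t[keep], np.log(mean[keep]), 1)[0]
        assert -1 / slope == pytest.approx(t_b, rel=0.15)

    def test_stoichiometry_below_one_rejected(self):
        with pytest.raises(ValueError, match="stoichiometr"):
            simulate_bleach_stack([((5.0, 5.0), 0)], seed=0)


class TestDiffusingFoci:
    def test_zero_diffusion_zero_error_is_stationary(self):
        obs, _ = simulate_diffusing_foci(0.0, 3, 10, sigma_loc_nm=0.0, seed=0)
        for track in obs:
            assert np.allclose(track, track[0])

    def test_step_variance_matches_2_D_dt(self):
        D = 0.5  # um^2/s
        obs, truth = simulate_diffusing_foci(D, 400, 30, 5.0,
                                             sigma_loc_nm=0.0, seed=1)
        steps = np.concatenate([np.diff(o, axis=0) for o in obs])
        var = steps.var(axis=0).mean()    # nm^2 per axis
        assert var == pytest.approx(2 * D * 5e-3 * 1e6, rel=0.05)

    def test_pure_localization_error_gives_4sigma2_msd(self):
        obs, _ = simulate_diffusing_foci(0.0, 300, 12, sigma_loc_nm=40.0,
                                         seed=3)
        d = np.concatenate([o[1:] - o[:-1] for o in obs])
        msd1 = (d ** 2).sum(axis=1).mean()
        assert msd1 == pytest.approx(4 * 40.0 ** 2, rel=0.1)


class TestFrapSimulator:
    def test_boundary_values(self):
        t = np.array([0.0, 1e6])
        f = simulate_frap(10.0, 0.2, 0.9, t, noise_sigma=0.0)
        assert f[0] == pytest.approx(0.2)
        assert f[-1] == pytest.approx(0.9)

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ValueError):
            simulate_frap(10.0, 0.9, 0.2, np.arange(5.0))
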