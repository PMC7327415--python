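"""Chung-Kennedy filtering, single-fluorophore intensity, stoichiometry and
copy-number estimation."""

import numpy as np
import pytest

from slimspore.simulate import NoiseModel, simulate_bleach_stack
from slimspore.stoichiometry import (CharacteristicIntensity, chung_kennedy,
                                     compartment_copy_number,
                                     estimate_characteristic_intensity,
                                     extrapolate_total, fit_bleach_time,
                                     fit_initial_intensity,
                                     membrane_fraction_in_focus,
                                     terminal_step_sizes)
from slimspore.tracking import overtrack, track_stack


class TestChungKennedy:
    def test_constant_trace_unchanged(self):
        x = np.full(50, 7.0)
        np.testing.assert_allclose(chung_kennedy(x), x)

    def test_noiseless_step_preserved_at_same_index(self):
        x = np.concatenate([np.full(25, 100.0), np.zeros(25)])
        y = chung_kennedy(x)
        # the edge stays sharp: values well away from the edge unchanged,
        # and the transition still happens between the same two indices
        assert y[20] == pytest.approx(100.0, abs=1.0)
        assert y[30] == pytest.approx(0.0, abs=1.0)
        assert y[24] > 50 > y[25]

    def test_white_noise_variance_reduced(self, rng):
        x = 50.0 + rng.normal(0, 5.0, 400)
        y = chung_kennedy(x)
        assert y.var() < 0.5 * x.var()

    def test_short_trace_identity(self):
        x = np.array([1.0, 2.0])
        np.testing.assert_array_equal(chung_kennedy(x), x)


class TestCharacteristicIntensity:
    def _traces(self, I_single=200.0, n_movies=4):
        noise = NoiseModel(background_offset=10, poisson=True,
                           gaussian_read_sigma=1, preset="custom")
        traces = []
        for seed in range(n_movies):
            stack, _ = simulate_bleach_stack(
                [((10 + 12 * (k % 3), 10 + 12 * (k // 3)), 4)
                 for k in range(9)],
                t_b_ms=100, I_single=I_single, n_frames=80, noise=noise,
                seed=seed, shape=(48, 48))
            tracks = [overtrack(stack, t) for t in track_stack(stack)
                      if t.included]
            traces += [t.intensities() for t in tracks]
        return traces

    def test_recovers_single_molecule_intensity_within_10pc(self):
        ci = estimate_characteristic_intensity(self._traces(I_single=200.0))
        assert ci.I_single == pytest.approx(200.0, rel=0.10)

    def test_identical_step_heights_give_that_height(self):
        h = 123.0
        traces = [np.concatenate([np.full(20, h), np.zeros(20)])
                  for _ in range(12)]
        ci = estimate_characteristic_intensity(traces)
        assert ci.I_single == pytest.approx(h, rel=0.02)

    def test_bimodal_contamination_mode_stays_at_singles(self, rng):
        traces = []
        for i in range(50):
            h = 100.0 if i % 10 else 200.0    # 10% doubles
            traces.append(np.concatenate([
                np.full(20, h) + rng.normal(0, 3, 20), np.zeros(20)]))
        ci = estimate_characteristic_intensity(traces)
        assert ci.I_single == pytest.approx(100.0, rel=0.1)

    def test_no_qualifying_steps_raises(self):
        rising = [np.linspace(0, 100, 30)] * 5
        with pytest.raises(ValueError):
            estimate_characteristic_intensity(rising)


class TestExponentialFits:
    def test_exact_exponential_recovered(self):
        t = np.array([0.0, 5.0, 10.0, 15.0])
        I = 100.0 * np.exp(-t / 100.0)
        fit = fit_initial_intensity(t, I, t_b_ms=100.0)
        assert fit.I0 == pytest.approx(100.0, rel=1e-9)

    def test_stoichiometry_one_for_single_fluorophore(self):
        t = np.array([0.0, 5.0, 10.0, 15.0])
        I = 150.0 * np.exp(-t / 100.0)
        fit = fit_initial_intensity(t, I, t_b_ms=100.0)
        assert fit.I0 / 150.0 == pytest.approx(1.0, rel=1e-9)

    def test_global_bleach_time_fit(self, rng):
        t = rng.uniform(0, 400, 3000)
        I = 800 * np.exp(-t / 100.0) * rng.lognormal(0, 0.2, 3000)
        fit = fit_bleach_time(t, I)
        assert fit.t_b_ms == pytest.approx(100.0, rel=0.15)

    def test_simulated_tetramers_peak_near_four(self):
        from slimspore.cluster import kde
        noise = NoiseModel(background_offset=5, poisson=True, preset="custom")
        stoichs = []
        I_single, t_b = 200.0, 100.0
        for seed in range(6):
            stack, _ = simulate_bleach_stack(
                [((10 + 12 * (k % 3), 10 + 12 * (k // 3)), 4)
                 for k in range(9)],
                t_b_ms=t_b, I_single=I_single, n_frames=40, noise=noise,
                seed=100 + seed, shape=(48, 48))
            for tr in track_stack(stack):
                if not tr.included or tr.foci[0].frame_index > 0:
                    continue
                fit = fit_initial_intensity(
                    tr.times_ms() - tr.times_ms()[0], tr.intensities(), t_b)
                stoichs.append(max(fit.I0, 0.0) / I_single)
        est = kde(np.array(stoichs), bandwidth=0.7)
        peak = est.grid[np.argmax(est.density)]
        assert peak == pytest.approx(4.0, abs=0.8)


class TestCopyNumber:
    def test_arithmetic(self):
        frame = np.full((10, 10), 100.0)
        mask = np.zeros((10, 10), dtype=bool)
        mask[:10, :10] = True
        est = compartment_copy_number(frame, mask, I_single=100.0,
                                      autofluor_per_px=20.0)
        assert est.copies == pytest.approx((10000 - 2000) / 100.0)

    def test_blank_compartment_zero(self):
        est = compartment_copy_number(np.zeros((5, 5)),
                                      np.ones((5, 5), bool), I_single=50.0)
        assert est.copies == 0.0

    def test_copy_number_linear_in_placed_molecules(self):
        from slimspore.simulate import render_spots
        rng = np.random.default_rng(4)
        I_single = 100.0
        recovered, placed = [], [50, 200, 800]
        for n in placed:
            xs = rng.uniform(10, 54, n)
            ys = rng.uniform(10, 54, n)
            frame = render_spots((64, 64), xs, ys, np.full(n, 1.33),
                                 np.full(n, I_single))
            est = compartment_copy_number(frame, np.ones((64, 64), bool),
                                          I_single)
            recovered.append(est.copies)
        slope = np.polyfit(placed, recovered, 1)[0]
        assert slope == pytest.approx(1.0, abs=0.1)


class TestMembraneFraction:
    def test_quarter_of_membrane_in_focus(self):
        frac = membrane_fraction_in_focus(0.9, 350.0)
        assert frac == pytest.approx(0.25, abs=0.02)
        assert 1 / frac == pytest.approx(4.0, abs=0.35)

    def test_extrapolation(self):
        assert extrapolate_total(32.0, 0.25) == pytest.approx(128.0)
        assert extrapolate_total(32.0, 1.0) == 32.0

    def test_dof_wider_than_cell_saturates(self):
        assert membrane_fraction_in_focus(0.3, 350.0) == 1.0
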