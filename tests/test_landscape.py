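"""Suitability-landscape construction, interpolation and derived fields."""

import numpy as np
import pandas as pd
import pytest

from foragersim import landscape as land


def flat_landscape(value=0.5, shape=(10, 10), cell_size=10.0, n_slices=1):
    layers = np.full((n_slices, *shape), value)
    starts = 120_000.0 - 2_000.0 * np.arange(n_slices)
    times = np.column_stack([starts, starts - 2_000.0])
    return land.SuitabilityLandscape((0.0, 0.0), cell_size, layers, times)


class TestConstruction:
    def test_two_slice_load_roundtrip(self, tmp_path):
        L = land.generate_synthetic_landscape((50, 50), 5.0, 2, 30.0, seed=7)
        index = land.save_landscape(L, str(tmp_path))
        files = sorted(str(p) for p in tmp_path.glob("slice_0*.asc"))
        L2 = land.load_landscape(files, index)
        assert L2.suitability.shape == (2, 50, 50)
        np.testing.assert_allclose(L2.suitability, L.suitability, atol=1e-6)
        np.testing.assert_array_equal(L2.slice_times, L.slice_times)

    def test_out_of_range_value_rejected(self, tmp_path):
        path = tmp_path / "bad.asc"
        land.write_ascii_grid(str(path), np.full((4, 4), 1.3), (0, 0), 10.0)
        idx = pd.DataFrame([{"slice_file": "bad.asc", "t_start_bp": 120_000,
                             "t_end_bp": 0}])
        with pytest.raises(land.LandscapeFormatError):
            land.load_landscape([str(path)], idx)

    def test_gap_in_time_index_rejected(self):
        layers = np.full((2, 4, 4), 0.5)
        times = np.array([[120_000.0, 80_000.0], [70_000.0, 0.0]])
        with pytest.raises(land.TimeIndexError):
            land.SuitabilityLandscape((0, 0), 10.0, layers, times)

    def test_overlapping_intervals_rejected(self):
        layers = np.full((2, 4, 4), 0.5)
        times = np.array([[120_000.0, 80_000.0], [90_000.0, 0.0]])
        with pytest.raises(land.TimeIndexError):
            land.SuitabilityLandscape((0, 0), 10.0, layers, times)

    def test_friction_shape_mismatch_rejected(self):
        with pytest.raises(land.LandscapeFormatError):
            land.SuitabilityLandscape(
                (0, 0), 10.0, np.full((1, 4, 4), 0.5),
                np.array([[120_000.0, 0.0]]), friction=np.zeros((3, 3)))


class TestSynthetic:
    def test_deterministic_given_seed(self):
        a = land.generate_synthetic_landscape((40, 40), 5.0, 3, 25.0, seed=11)
        b = land.generate_synthetic_landscape((40, 40), 5.0, 3, 25.0, seed=11)
        np.testing.assert_array_equal(a.suitability, b.suitability)

    def test_slices_differ(self):
        L = land.generate_synthetic_landscape((40, 40), 5.0, 2, 25.0, seed=1)
        assert not np.allclose(L.suitability[0], L.suitability[1])

    def test_barrier_column_fully_impassable(self):
        bar = land.BarrierSpec("vertical", position_km=100.0, width_km=10.0)
        L = land.generate_synthetic_landscape((40, 40), 5.0, 1, 25.0,
                                              barrier=bar, seed=2)
        col = slice(19, 21)  # cells with centres at 97.5 and 102.5 km
        assert np.all(L.friction[:, col] == 1.0)
        assert np.all(L.suitability[0][:, col] == 0.0)

    def test_smoothness_controls_correlation_length(self):
        """Larger correlation length -> slower falloff of autocorrelation."""
        def lag_corr(field, lag):
            a = field[:, :-lag].ravel() - field.mean()
            b = field[:, lag:].ravel() - field.mean()
            return float((a * b).mean() / field.var())

        smooth = land.generate_synthetic_landscape((80, 80), 5.0, 1, 100.0,
                                                   seed=3).suitability[0]
        rough = land.generate_synthetic_landscape((80, 80), 5.0, 1, 10.0,
                                                  seed=3).suitability[0]
        assert lag_corr(smooth, 4) > lag_corr(rough, 4)


class TestInterpolation:
    def test_cell_centre_identity(self):
        L = flat_landscape()
        L.suitability[0, 3, 4] = 0.9
        # centre of cell (row 3, col 4): x = 45, y = 35
        assert land.suitability_at(L, np.array([45.0, 35.0]), 119_000) == \
            pytest.approx(0.9)

    def test_bilinear_midpoint(self):
        L = flat_landscape(0.2)
        L.suitability[0, :, 5] = 0.6   # column x-centre 55; column 4 is 0.2
        val = land.suitability_at(L, np.array([50.0, 35.0]), 119_000)
        assert val == pytest.approx(0.4)

    def test_outside_domain_is_zero(self):
        L = flat_landscape(0.8)
        assert land.suitability_at(L, np.array([-5.0, 50.0]), 119_000) == 0.0
        L.domain_mask[2, 2] = False
        assert land.suitability_at(L, np.array([25.0, 25.0]), 119_000) == 0.0

    def test_piecewise_constant_in_time(self):
        L = land.generate_synthetic_landscape((20, 20), 5.0, 2, 20.0, seed=5)
        x = np.array([50.0, 50.0])
        s_early = land.suitability_at(L, x, 119_500.0)
        assert land.suitability_at(L, x, 118_100.0) == s_early
        assert land.suitability_at(L, x, 117_900.0) != s_early

    def test_time_outside_horizon(self):
        L = flat_landscape()
        with pytest.raises(land.TimeOutsideHorizonError):
            land.suitability_at(L, np.array([5.0, 5.0]), 121_000)


class TestPotentialGradient:
    def test_flat_field_zero_gradient(self):
        L = flat_landscape(0.7)
        p = land.LandscapeParams()
        g = land.potential_gradient(L, p, np.array([43.0, 57.0]), 119_000)
        np.testing.assert_array_equal(g, [0.0, 0.0])

    def test_linear_field_gradient(self):
        """s increasing in x with slope g gives grad V = (-w_env*g, 0)."""
        L = flat_landscape()
        xs, _ = L.cell_centers()
        slope = 0.005
        L.suitability[0] = slope * xs[None, :]
        p = land.LandscapeParams(w_env=2.0)
        g = land.potential_gradient(L, p, np.array([50.0, 50.0]), 119_000)
        assert g[0] == pytest.approx(-2.0 * slope)
        assert g[1] == pytest.approx(0.0)

    def test_gradient_small_at_suitability_maximum(self):
        L = land.generate_synthetic_landscape((60, 60), 5.0, 1, 40.0, seed=9)
        p = land.LandscapeParams()
        interior = L.suitability[0][5:-5, 5:-5]
        r, c = np.unravel_index(np.argmax(interior), interior.shape)
        xs, ys = L.cell_centers()
        x = np.array([xs[c + 5], ys[r + 5]])
        g = land.potential_gradient(L, p, x, 119_000)
        assert np.linalg.norm(g) < 0.01


class TestSigma:
    def test_uniform_sigma_without_friction(self):
        L = flat_landscape()
        p = land.LandscapeParams(sigma0=0.4)
        assert land.sigma_at(L, p, np.array([33.0, 71.0])) == pytest.approx(0.4)

    def test_barrier_sigma_zero(self):
        L = flat_landscape()
        L.friction = np.zeros(L.shape)
        L.friction[5, 5] = 1.0
        p = land.LandscapeParams(sigma0=0.4)
        assert land.sigma_at(L, p, np.array([55.0, 55.0])) <= 4e-7

    def test_linear_friction_scaling(self):
        L = flat_landscape()
        L.friction = np.full(L.shape, 0.5)
        p = land.LandscapeParams(sigma0=0.4)
        assert land.sigma_at(L, p, np.array([55.0, 55.0])) == pytest.approx(0.2)


class TestCarryingCapacity:
    def test_zero_suitability_zero_capacity(self):
        L = flat_landscape(0.0)
        p = land.LandscapeParams()
        assert land.carrying_capacity(L, p, np.array([50.0, 50.0]),
                                      119_000, 20.0) == 0.0

    def test_full_disc_value(self):
        """K on a fully suitable fine grid ~ kappa * pi * r^2."""
        layers = np.ones((1, 100, 100))
        L = land.SuitabilityLandscape((0, 0), 1.0, layers,
                                      np.array([[120_000.0, 0.0]]))
        p = land.LandscapeParams(kappa=0.05)
        K = land.carrying_capacity(L, p, np.array([50.0, 50.0]), 100_000, 20.0)
        assert K == pytest.approx(0.05 * np.pi * 400.0, rel=0.05)

    def test_linear_in_kappa(self):
        L = land.generate_synthetic_landscape((30, 30), 5.0, 1, 20.0, seed=4)
        x = np.array([70.0, 70.0])
        K1 = land.carrying_capacity(L, land.LandscapeParams(kappa=0.1), x,
                                    119_000, 20.0)
        K2 = land.carrying_capacity(L, land.LandscapeParams(kappa=0.2), x,
                                    119_000, 20.0)
        assert K2 == pytest.approx(2 * K1)

    def test_monotone_under_pointwise_increase(self):
        L = land.generate_synthetic_landscape((30, 30), 5.0, 1, 20.0, seed=4)
        raised = land.SuitabilityLandscape(
            L.origin, L.cell_size, np.clip(L.suitability + 0.1, 0, 1),
            L.slice_times.copy())
        p = land.LandscapeParams()
        x = np.array([75.0, 75.0])
        assert land.carrying_capacity(raised, p, x, 119_000, 20.0) >= \
            land.carrying_capacity(L, p, x, 119_000, 20.0)

    def test_grid_matches_point_function_at_cell_centres(self):
        L = land.generate_synthetic_landscape((25, 25), 5.0, 1, 20.0, seed=6)
        p = land.LandscapeParams()
        grid = land.carrying_capacity_grid(L, p, 0, 20.0)
        xs, ys = L.cell_centers()
        for r, c in [(5, 5), (12, 18), (20, 3)]:
            direct = land.carrying_capacity(
                L, p, np.array([xs[c], ys[r]]), 119_000, 20.0)
            assert grid[r, c] == pytest.approx(direct)


class TestEquilibriumSampling:
    def test_two_cell_proportions(self):
        layers = np.zeros((1, 1, 2))
        layers[0, 0] = [0.9, 0.1]
        L = land.SuitabilityLandscape((0, 0), 10.0, layers,
                                      np.array([[120_000.0, 0.0]]))
        pos = land.sample_equilibrium_positions(L, 119_000, 10_000, seed=0)
        frac = (pos[:, 0] < 10.0).mean()
        assert frac == pytest.approx(0.9, abs=0.01)

    def test_zero_cells_never_sampled(self):
        layers = np.zeros((1, 2, 2))
        layers[0, 0, 0] = 1.0
        L = land.SuitabilityLandscape((0, 0), 10.0, layers,
                                      np.array([[120_000.0, 0.0]]))
        pos = land.sample_equilibrium_positions(L, 119_000, 500, seed=1)
        assert np.all(pos < 10.0)

    def test_deterministic_given_seed(self):
        L = land.generate_synthetic_landscape((20, 20), 5.0, 1, 20.0, seed=2)
        a = land.sample_equilibrium_positions(L, 119_000, 50, seed=42)
        b = land.sample_equilibrium_positions(L, 119_000, 50, seed=42)
        np.testing.assert_array_equal(a, b)

    def test_all_zero_landscape_rejected(self):
        L = flat_landscape(0.0)
        with pytest.raises(ValueError):
            land.sample_equilibrium_positions(L, 119_000, 10, seed=0)
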