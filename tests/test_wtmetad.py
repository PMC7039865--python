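import numpy as np
import pytest

from porekit import wtmetad as wm
from porekit.exceptions import (
    ConfigurationError,
    GeometryError,
    IntegrationError,
)

KT310 = wm.KB * 310.0


class TestCollectiveVariable:
    def test_three_four_five(self):
        s, comps = wm.cv_value(np.array([3.0, 4.0, 0.0]), np.zeros((4, 3)))
        assert s == pytest.approx(5.0)
        np.testing.assert_allclose(comps, [3.0, 4.0, 0.0])

    def test_ion_at_com(self):
        anchors = np.array([[1.0, 0, 0], [-1.0, 0, 0], [0, 1.0, 0], [0, -1.0, 0]])
        s, _ = wm.cv_value(np.zeros(3), anchors)
        assert s == 0.0

    def test_unit_mass_com(self):
        anchors = np.array([[1.0, 0, 0], [-1.0, 0, 0], [0, 1.0, 0], [0, -1.0, 0]])
        s, comps = wm.cv_value(np.array([0.0, 0.0, 7.0]), anchors)
        assert s == pytest.approx(7.0)
        np.testing.assert_allclose(comps, [0.0, 0.0, 7.0])

    def test_empty_anchor_group(self):
        with pytest.raises(ConfigurationError):
            wm.cv_value(np.zeros(3), np.empty((0, 3)))


class TestBias:
    def test_no_hills_zero_everywhere(self):
        state = wm.BiasState()
        assert state.bias_energy(7.3) == 0.0
        assert state.deposit_hill(10.0) == pytest.approx(state.h0)

    def test_single_hill_closed_form(self):
        state = wm.BiasState(sigma=1.0, h0=1.0,
                             centers=[10.0], heights=[1.0])
        assert state.bias_energy(10.0) == pytest.approx(1.0)
        assert state.bias_energy(11.0) == pytest.approx(np.exp(-0.5))

    def test_revisited_heights_decay_monotonically(self):
        state = wm.BiasState(sigma=0.5, h0=1.0, bias_factor=5.0)
        heights = [state.deposit_hill(10.0) for _ in range(1000)]
        assert all(b < a for a, b in zip(heights, heights[1:]))
        assert heights[-1] < 0.05 * heights[0]

    def test_gamma_must_exceed_one(self):
        with pytest.raises(ConfigurationError):
            wm.BiasState(bias_factor=1.0)

    def test_bias_force_matches_numerical_gradient(self):
        state = wm.BiasState(sigma=0.7, centers=[8.0, 9.5, 11.0],
                             heights=[1.2, 0.9, 0.5])
        for s in (7.0, 8.8, 10.2):
            h = 1e-6
            numerical = (state.bias_energy(s + h) - state.bias_energy(s - h)) / (2 * h)
            assert state.bias_dV_ds(s) == pytest.approx(numerical, rel=1e-5)


class TestWallRestraint:
    def test_zero_inside(self):
        wall = wm.WallRestraint(5.0, 20.0, 10.0)
        assert wall.energy(12.0) == 0.0
        assert wall.dE_ds(12.0) == 0.0

    def test_quadratic_outside(self):
        wall = wm.WallRestraint(5.0, 20.0, 10.0)
        assert wall.energy(22.0) == pytest.approx(40.0)  # 10·(22−20)²
        assert wall.energy(4.0) == pytest.approx(10.0)

    def test_force_matches_numerical_gradient(self):
        wall = wm.WallRestraint(5.0, 20.0, 7.0)
        for s in (3.5, 21.2, 25.0):
            h = 1e-6
            numerical = (wall.energy(s + h) - wall.energy(s - h)) / (2 * h)
            assert wall.dE_ds(s) == pytest.approx(numerical, rel=1e-5)

    def test_bounds_order_enforced(self):
        with pytest.raises(ConfigurationError):
            wm.WallRestraint(20.0, 5.0)


class TestAngleRestraint:
    def _restraint(self, max_angle=80.0):
        # A = upper-leaflet P COM (vertex), B = lower-leaflet P COM
        return wm.AngleRestraint(
            point_a=np.array([0.0, 0.0, 100.0]),
            point_b=np.array([0.0, 0.0, 60.0]),
            max_angle_deg=max_angle,
            force_constant=50.0,
        )

    def test_small_angle_no_penalty(self):
        r = self._restraint()
        ion = np.array([3.0, 0.0, 70.0])  # ~5.7° off the A→B axis
        energy, force = r.energy_force(ion)
        assert energy == 0.0
        np.testing.assert_allclose(force, 0.0)

    def test_right_angle_penalized(self):
        r = self._restraint()
        ion = np.array([10.0, 0.0, 100.0])  # 90° at the vertex
        assert r.angle(ion) == pytest.approx(np.pi / 2)
        energy, _ = r.energy_force(ion)
        expected = 50.0 * (np.deg2rad(90.0) - np.deg2rad(80.0)) ** 2
        assert energy == pytest.approx(expected)

    def test_force_matches_numerical_gradient(self):
        r = self._restraint(max_angle=30.0)
        ion = np.array([20.0, 5.0, 90.0])  # ~64° at the vertex
        energy, force = r.energy_force(ion)
        assert energy > 0
        h = 1e-6
        for k in range(3):
            dp = np.zeros(3)
            dp[k] = h
            e_plus = r.energy_force(ion + dp)[0]
            e_minus = r.energy_force(ion - dp)[0]
            numerical = -(e_plus - e_minus) / (2 * h)
            assert force[k] == pytest.approx(numerical, rel=1e-5, abs=1e-8)

    def test_coincident_points_rejected(self):
        r = self._restraint()
        with pytest.raises(GeometryError):
            r.angle(np.array([0.0, 0.0, 100.0]))


class TestLangevinIntegrator:
    def test_free_diffusion_msd_slope(self):
        """MSD of a free particle grows as 2·D·t with D = k_B T/ξ."""
        run = wm.run_langevin_metad(
            lambda x: 0.0, lambda x: np.zeros(1), np.zeros(1),
            n_steps=100_000, dt=0.01, temperature=310.0, friction=1.0,
            seed=11, sample_stride=100,
        )
        x = run.positions[:, 0]
        d_eff = KT310 / 1.0
        # lag of one sample (100 steps): ~1000 independent increments
        msd1 = ((x[1:] - x[:-1]) ** 2).mean()
        assert msd1 == pytest.approx(2.0 * d_eff * 1.0, rel=0.10)
        # linear growth: tenfold lag gives ~tenfold MSD
        msd10 = ((x[10:] - x[:-10]) ** 2).mean()
        assert msd10 / msd1 == pytest.approx(10.0, rel=0.25)

    def test_harmonic_well_boltzmann_variance(self):
        """Sampled variance in U = ½kx² matches k_B T/k."""
        k = 5.0
        run = wm.run_langevin_metad(
            lambda x: 0.5 * k * float(x[0] ** 2),
            lambda x: k * x,
            np.zeros(1), n_steps=200_000, dt=0.005, temperature=310.0,
            friction=1.0, seed=12, sample_stride=20,
        )
        x = run.positions[5000:, 0]
        assert x.var() == pytest.approx(KT310 / k, rel=0.10)
        assert abs(x.mean()) < 3 * np.sqrt(KT310 / k / x.size) * 10

    def test_determinism_under_fixed_seed(self):
        args = dict(
            n_steps=5_000, dt=0.005, temperature=310.0, friction=1.0,
            seed=13, sample_stride=10,
        )
        u, du = wm.double_well(8.0, 14.0, 5 * KT310)
        a = wm.run_langevin_metad(u, du, np.array([8.0]), bias=wm.BiasState(),
                                  **args)
        b = wm.run_langevin_metad(u, du, np.array([8.0]), bias=wm.BiasState(),
                                  **args)
        np.testing.assert_array_equal(a.positions, b.positions)

    def test_divergence_reported(self):
        with pytest.raises(IntegrationError):
            wm.run_langevin_metad(
                lambda x: -100.0 * float(x[0] ** 2),
                lambda x: -200.0 * x,
                np.array([1.0]), n_steps=10_000, dt=0.1, temperature=310.0,
                friction=0.1, seed=14,
            )

    def test_bias_escapes_double_well_unbiased_stays(self):
        """With hills both wells are visited; unbiased low-T dynamics stay
        trapped over the same budget."""
        u, du = wm.double_well(8.0, 14.0, 10 * KT310)
        common = dict(n_steps=150_000, dt=0.005, temperature=310.0,
                      friction=1.0, seed=15)
        biased = wm.run_langevin_metad(
            u, du, np.array([8.0]), bias=wm.BiasState(),
            wall=wm.WallRestraint(), **common,
        )
        unbiased = wm.run_langevin_metad(
            u, du, np.array([8.0]), wall=wm.WallRestraint(), **common,
        )
        assert biased.cv_values.max() > 13.0  # reached the second well
        assert unbiased.cv_values.max() < 11.0  # never crossed the barrier


class TestFesReconstruction:
    def test_single_hill_mirrored_gaussian(self):
        state = wm.BiasState(sigma=1.0, h0=1.0, bias_factor=10.0,
                             temperature=310.0,
                             centers=[10.0], heights=[1.0])
        grid = np.linspace(8.0, 12.0, 81)
        F = wm.reconstruct_fes_1d(state, grid, average_from=1.0)
        scale = 10.0 / 9.0
        expected = scale * (1.0 - np.exp(-((grid - 10.0) ** 2) / 2.0))
        np.testing.assert_allclose(F, expected, atol=1e-12)

    def test_symmetric_double_well_minima(self):
        u, du = wm.double_well(8.0, 14.0, 5 * KT310)
        bias = wm.BiasState()
        wm.run_langevin_metad(
            u, du, np.array([8.0]), n_steps=300_000, dt=0.005,
            temperature=310.0, friction=1.0, seed=16, bias=bias,
            wall=wm.WallRestraint(),
        )
        grid = np.linspace(6.0, 16.0, 201)
        F = wm.reconstruct_fes_1d(bias, grid)
        # the two deepest local minima sit near the true well positions
        minima = [
            k for k in range(1, 200)
            if F[k] <= F[k - 1] and F[k] <= F[k + 1]
        ]
        minima.sort(key=lambda k: F[k])
        wells = sorted(grid[k] for k in minima[:2])
        assert wells[0] == pytest.approx(8.0, abs=0.5)
        assert wells[1] == pytest.approx(14.0, abs=0.5)

    def test_projection_masks_unvisited_cells(self):
        u, du = wm.double_well(8.0, 14.0, 5 * KT310)
        bias = wm.BiasState()
        anchors = np.zeros((4, 3))
        run = wm.run_langevin_metad(
            u, du, np.array([8.0, 0.0, 0.0]), n_steps=50_000, dt=0.005,
            temperature=310.0, friction=1.0, seed=17,
            cv=wm.distance_cv(anchors), bias=bias, wall=wm.WallRestraint(),
        )
        F, xe, ye = wm.project_fes_2d(run, (0, 1), bins=30)
        assert np.isnan(F).any()  # far corners never sampled
        assert np.nanmin(F) == pytest.approx(0.0)

    def test_empty_bias_rejected(self):
        with pytest.raises(Exception):
            wm.reconstruct_fes_1d(wm.BiasState(), np.linspace(0, 1, 10))
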