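"""Field integration, adhesion term, polarity process, and the
persistent-random-walk limit."""

import numpy as np
import pytest
from scipy import stats

from cellstrand.dynamics import (
    CellRecord,
    adhesion_rate,
    center_of_mass,
    field_rhs,
    msd_closed_form,
    point_trajectories,
    saturating_grad,
    spawn_cell_rngs,
    stable_dt,
    step_fields,
    step_polarity,
)
from cellstrand.energetics import ModelParams, interface_width
from cellstrand.fields import GridSpec, PhaseFieldState, tanh_disk

from conftest import make_cell_state


class TestSaturatingGrad:
    def test_zero_maps_to_zero(self):
        assert np.allclose(saturating_grad(np.zeros((2, 4, 4)), 1.0), 0.0)

    def test_linear_at_small_argument(self):
        z = np.array([1e-6, -2e-6]).reshape(2, 1)
        f = saturating_grad(z, 1.0)
        assert np.allclose(f, z, rtol=1e-11)

    def test_bounded_by_analytic_supremum(self):
        # |f| = |z|/(1+eps|z|^2) has supremum 1/(2 sqrt(eps)) at |z|=1/sqrt(eps)
        for eps in (0.25, 1.0, 4.0):
            mags = np.geomspace(1e-3, 1e6, 200)
            z = np.stack([mags, np.zeros_like(mags)])
            f = saturating_grad(z, eps)
            assert np.max(np.abs(f)) <= 1.0 / (2 * np.sqrt(eps)) + 1e-12

    def test_requires_positive_eps(self):
        with pytest.raises(ValueError):
            saturating_grad(np.zeros((2, 2)), 0.0)


class TestAdhesionRate:
    def test_isolated_cell_no_walls_is_zero(self, single_cell):
        state, cells = single_cell
        p = ModelParams(omega=50.0, kappa=50.0)
        assert np.allclose(adhesion_rate(state, 0, cells, p), 0.0, atol=1e-12)

    def test_zero_strengths_give_zero(self, two_cells):
        state, cells = two_cells
        p = ModelParams(omega=0.0, kappa=0.0)
        assert np.allclose(adhesion_rate(state, 0, cells, p), 0.0)

    def test_two_front_fixture_pulls_mass_toward_neighbor(self, soft_params):
        """1-D fixture: two abutting fronts; the adhesion term shifts each
        cell's mass toward its neighbor, matching a nodewise evaluation."""
        grid = GridSpec(96, 8, 0.5, "periodic", "periodic")
        p = soft_params.with_(omega=30.0, kappa=0.0)
        d = interface_width(p)
        x, _ = grid.coords()
        ell = d / (2 * np.log(9.0))
        # cell 0 occupies x<20, cell 1 occupies x>26 (gap ~ interface width)
        phi0 = 1.0 / (1.0 + np.exp((x - 20.0) / ell))
        phi1 = 1.0 / (1.0 + np.exp(-(x - 26.0) / ell))
        state = PhaseFieldState(np.stack([phi0, phi1]), np.zeros(grid.shape), grid)
        cells = [CellRecord(id=0, theta=0.0), CellRecord(id=1, theta=0.0)]
        adh0 = adhesion_rate(state, 0, cells, p)
        # nodewise oracle: omega * f(grad phi1) . grad phi0
        from cellstrand.fields import gradient

        g0 = np.stack(gradient(state.phi[0], grid))
        g1 = np.stack(gradient(state.phi[1], grid))
        f1 = saturating_grad(g1, p.eps)
        oracle = p.omega * (f1[0] * g0[0] + f1[1] * g0[1])
        assert np.allclose(adh0, oracle, atol=1e-12)
        # the update term enters the dynamics with a minus sign: mass of
        # cell 0 grows on the side facing cell 1
        dphi0 = -adh0
        row = dphi0[4]
        gap = (x[4] > 20.0) & (x[4] < 26.0)
        assert row[gap].sum() > 0

    def test_unknown_cell_raises(self, single_cell, soft_params):
        state, cells = single_cell
        with pytest.raises(KeyError):
            adhesion_rate(state, 3, cells, soft_params)


class TestStepFields:
    def test_relaxed_cell_is_fixed_point(self, single_cell, soft_params):
        state, cells = single_cell
        relax = soft_params.with_(p0=0.0)
        dt = stable_dt(relax, state.grid.h)
        for _ in range(int(2.0 / dt)):
            step_fields(state, cells, dt, relax)
        before = state.phi.copy()
        step_fields(state, cells, dt, relax)
        assert np.max(np.abs(state.phi - before)) < 1e-4

    def test_pure_advection_translates_field(self, soft_params):
        grid = GridSpec(48, 48, 1.0, "periodic", "periodic")
        p = soft_params.with_(alpha=0.0, K=0.0, lam=0.0, g=0.0, g_wall=0.0,
                              omega=0.0, kappa=0.0, p0=10.0)
        # a wide interface keeps the spectral content resolvable, so the
        # dispersion error of the central stencil stays small
        phi = tanh_disk(grid, (24.0, 24.0), 0.95 * p.R, 8.0)[None]
        state = PhaseFieldState(phi, np.zeros(grid.shape), grid)
        cells = [CellRecord(id=0, theta=0.0)]  # advect along +x at p0
        ref = state.phi[0].copy()
        n = 100
        dt = 0.01
        for _ in range(n):
            step_fields(state, cells, dt, p, impl="numpy")
        shift = p.p0 * n * dt / grid.h  # 10 nodes
        expected = np.roll(ref, int(round(shift)), axis=-1)
        err = np.max(np.abs(state.phi[0] - expected))
        assert err < 0.05  # dispersion-limited

    def test_permuting_cell_ids_leaves_trajectory_identical(self, soft_params):
        grid = GridSpec(40, 40, 1.0, "periodic", "periodic")
        p = soft_params.with_(omega=20.0)
        centers = [(14.0, 20.0), (27.0, 20.0)]
        state1, cells1 = make_cell_state(grid, p, centers)
        state2, cells2 = make_cell_state(grid, p, centers[::-1])
        for c, th in zip(cells1, (0.3, 2.0)):
            c.theta = th
        for c, th in zip(cells2, (2.0, 0.3)):
            c.theta = th
        dt = 0.005
        for _ in range(20):
            step_fields(state1, cells1, dt, p)
            step_fields(state2, cells2, dt, p)
        assert np.array_equal(state1.phi[0], state2.phi[1])
        assert np.array_equal(state1.phi[1], state2.phi[0])

    def test_divergence_raises_floating_point_error(self, single_cell, soft_params):
        state, cells = single_cell
        huge = soft_params.with_(p0=1e8)
        with pytest.raises(FloatingPointError):
            for _ in range(50):
                step_fields(state, cells, 0.05, huge)

    def test_numba_and_numpy_paths_agree(self, soft_params):
        grid = GridSpec(32, 40, 1.0, "periodic", "walled")
        p = soft_params.with_(omega=40.0, kappa=30.0, g=80.0)
        state, cells = make_cell_state(grid, p, [(10.0, 16.0), (22.0, 16.0)])
        state.wall = tanh_disk(grid, (16.0, 34.0), 6.0, 3.0)
        cells[0].theta = 1.0
        cells[1].theta = -2.0
        r_np = field_rhs(state, cells, p, impl="numpy")
        pytest.importorskip("numba")
        r_nb = field_rhs(state, cells, p, impl="numba")
        # the compiled path truncates sub-1e-6 field tails outside the
        # support boxes, so agreement is to that tolerance, not rounding
        assert np.max(np.abs(r_np - r_nb)) < 1e-6 * max(1.0, np.max(np.abs(r_np)))


class TestSteadySpeed:
    """An equilibrated isolated cell advected by its polarity travels at
    the polarity magnitude (the shape is a traveling-wave solution)."""

    @pytest.mark.parametrize("state_name,factor", [("guided", 2.0), ("leader", 3.0)])
    def test_isolated_cell_speed_matches_polarity(self, state_name, factor):
        p = ModelParams(omega=0.0, kappa=0.0)
        d = interface_width(p)
        grid = GridSpec(60, 60, 1.0, "periodic", "periodic")
        phi = tanh_disk(grid, (30.0, 30.0), 0.95 * p.R, d)[None]
        state = PhaseFieldState(phi, np.zeros(grid.shape), grid)
        cells = [CellRecord(id=0, theta=np.pi / 2, state=state_name)]
        dt = stable_dt(p, grid.h)
        relax = p.with_(p0=0.0)
        for _ in range(int(0.4 / dt)):
            step_fields(state, cells, dt, relax)
        for _ in range(int(0.2 / dt)):
            step_fields(state, cells, dt, p)
        y0 = center_of_mass(state, 0)[1]
        t0 = state.t
        for _ in range(int(0.5 / dt)):
            step_fields(state, cells, dt, p)
        dy = (center_of_mass(state, 0)[1] - y0) % grid.extent[1]
        speed = dy / (state.t - t0)
        assert speed == pytest.approx(factor * p.p0, rel=0.10)


class TestPolarity:
    def test_deterministic_relaxation_to_preferred_angle(self, params):
        p = params.with_(D_r=0.0, k_theta=2.0)
        cells = [CellRecord(id=0, theta=2.5, state="guided", theta0=0.5)]
        rngs = spawn_cell_rngs(0, 1)
        dt = 0.001
        n = 1000
        for _ in range(n):
            step_polarity(cells, dt, p, rngs)
        expected = 0.5 + 2.0 * np.exp(-p.k_theta * n * dt)
        assert cells[0].theta == pytest.approx(expected, rel=0.01)

    def test_follower_ignores_chemotaxis(self, params):
        p = params.with_(D_r=0.0, k_theta=5.0)
        cells = [CellRecord(id=0, theta=2.0, state="follower", theta0=0.0)]
        step_polarity(cells, 0.1, p, spawn_cell_rngs(0, 1))
        assert cells[0].theta == 2.0

    def test_free_diffusion_variance_grows_linearly(self, params):
        p = params.with_(k_theta=0.0)
        n = 10_000
        cells = [CellRecord(id=i, theta=0.0, state="follower") for i in range(n)]
        rngs = spawn_cell_rngs(123, n)
        dt, steps = 0.01, 50
        for _ in range(steps):
            step_polarity(cells, dt, p, rngs)
        t = dt * steps
        var = np.var([c.theta for c in cells])
        expected = 2 * p.D_r * t
        se = expected * np.sqrt(2.0 / n)
        assert abs(var - expected) < 3 * se

    def test_stationary_ou_variance_and_normality(self, params):
        """theta - theta0 reaches the Gaussian stationary law with variance
        D_r / k_theta."""
        p = params  # defaults: D_r=1.344/h, k_theta=0.84/h
        n = 10_000
        rngs = spawn_cell_rngs(7, n)
        target_var = p.D_r / p.k_theta
        cells = [
            CellRecord(
                id=i,
                theta=float(rngs[i].normal(0.0, np.sqrt(target_var))),
                state="guided",
                theta0=0.0,
            )
            for i in range(n)
        ]
        dt = 0.02
        for _ in range(200):  # 4 h >> 1/k_theta
            step_polarity(cells, dt, p, rngs)
        thetas = np.array([c.theta for c in cells])
        se = target_var * np.sqrt(2.0 / n)
        assert abs(np.var(thetas) - target_var) < 3 * se + 0.02
        ks = stats.kstest(thetas / np.sqrt(target_var), "norm")
        assert ks.pvalue > 0.01


class TestCenterOfMass:
    def test_symmetric_disk_center(self, periodic_grid, soft_params):
        state, _ = make_cell_state(periodic_grid, soft_params, [(20.0, 30.0)])
        c = center_of_mass(state, 0)
        assert c[0] == pytest.approx(20.0, abs=0.1)
        assert c[1] == pytest.approx(30.0, abs=0.1)

    def test_translation_including_periodic_wrap(self, soft_params):
        grid = GridSpec(40, 40, 1.0, "periodic", "periodic")
        state, _ = make_cell_state(grid, soft_params, [(20.0, 20.0)])
        shifted = PhaseFieldState(
            np.roll(state.phi, 15, axis=-1), state.wall, grid
        )
        c = center_of_mass(shifted, 0)
        assert c[0] == pytest.approx((20.0 + 15.0) % 40.0, abs=0.05)

    def test_vanished_cell_flagged(self, periodic_grid, soft_params):
        phi = np.zeros((1, *periodic_grid.shape))
        state = PhaseFieldState(phi, np.zeros(periodic_grid.shape), periodic_grid)
        from cellstrand.dynamics import center_of_mass_all

        cx, cy = center_of_mass_all(state)
        assert np.isnan(cx[0]) and np.isnan(cy[0])


class TestPointTrajectoriesMSD:
    def test_follower_msd_matches_closed_form(self, params):
        """Free persistent random walk: MSD(t) = (2 p0^2/D_r^2)(D_r t +
        exp(-D_r t) - 1), approached within sampling error."""
        n = 150
        times, xy = point_trajectories(n, t_max=6.0, dt=0.01, params=params,
                                       seed=42, record_every=25)
        disp2 = ((xy - xy[0]) ** 2).sum(axis=-1)  # (frames, n)
        msd = disp2.mean(axis=1)
        expected = msd_closed_form(times, params.p0, params.D_r)
        se = disp2.std(axis=1, ddof=1) / np.sqrt(n)
        late = times > 0.5
        assert np.all(np.abs(msd[late] - expected[late]) < 3 * se[late])

    def test_long_time_slope_is_4_D0(self, params):
        n = 200
        times, xy = point_trajectories(n, t_max=12.0, dt=0.01, params=params,
                                       seed=3, record_every=50)
        disp2 = ((xy - xy[0]) ** 2).sum(axis=-1).mean(axis=1)
        late = times > 3.0 / params.D_r
        slope = np.polyfit(times[late], disp2[late], 1)[0]
        D0 = params.p0**2 / (2 * params.D_r)
        assert slope == pytest.approx(4 * D0, rel=0.2)
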