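"""Solver physics: stability bounds, analytic oracles, conservation."""

import math

import numpy as np
import pytest

import periclear as pc
from periclear.errors import SolverDivergenceError
from periclear.params import custom_case
from periclear.solver import FieldState, TransportOperator

from conftest import interp_distance


class TestStableDt:
    def test_advection_limited_matches_reference_mesh(self, params):
        # no diffusion: the CFL bound alone governs -> 0.14 s on a 2.36 um mesh
        grid = pc.make_calibration_domain(2.36e-5, 2.36e-5, 2.36e-6)
        p = params.replace(D_star=0.0)
        op = TransportOperator(grid, p, pc.build_case("C1"))
        assert op.stable_dt() == pytest.approx(0.1417, abs=5e-4)

    def test_diffusion_limited_cap(self, params):
        # all velocities zero, D = 8.7e-11, dx = 20 um -> 0.9*dx^2/(4D) ~ 1.03 s
        grid = pc.make_calibration_domain(2e-3, 2e-3, 20e-6)
        op = TransportOperator(grid, params, pc.build_case("A1"))
        assert op.stable_dt() == pytest.approx(0.9 * (2e-5) ** 2 / (4 * 8.7e-11), rel=1e-9)
        assert op.stable_dt() == pytest.approx(1.03, rel=0.01)

    def test_advective_bound_linear_in_dx(self, params):
        p = params.replace(D_star=0.0)
        dts = []
        for dx in (2.36e-6, 4.72e-6):
            grid = pc.make_calibration_domain(40 * dx, 40 * dx, dx)
            dts.append(TransportOperator(grid, p, pc.build_case("C1")).stable_dt())
        assert dts[1] == pytest.approx(2 * dts[0], rel=1e-9)


class TestTwoCompartmentExchange:
    def test_pure_uptake_matches_two_box_ode(self, params):
        """With D = u = u_b = 0, c decays as c0 e^{-k t} and c_b gains it."""
        grid = pc.make_calibration_domain(1e-3, 1e-3, 50e-6)
        p = params.replace(D_star=0.0, t_inject=0.0)
        op = TransportOperator(grid, p, custom_case(diffusion=1, uptake=1),
                               injection_mode="no_flux")
        state = FieldState.zeros(grid)
        state.c[:] = p.c0
        dt, T = 1.0, 1000.0
        for _ in range(int(T / dt)):
            state = op.step(state, dt)
        k = p.k_b
        assert np.allclose(state.c, p.c0 * math.exp(-k * T), rtol=1e-3)
        assert np.allclose(state.c_b, p.c0 * (1 - math.exp(-k * T)), rtol=1e-3)
        # total is conserved exactly (take-up is exchange, not loss)
        assert np.allclose(state.c + state.c_b, p.c0, rtol=1e-12)

    def test_null_dynamics(self, params):
        grid = pc.make_calibration_domain(1e-3, 1e-3, 50e-6)
        p = params.replace(D_star=0.0, t_inject=0.0)
        op = TransportOperator(grid, p, custom_case(diffusion=1),
                               injection_mode="no_flux")
        state = FieldState.zeros(grid)
        state.c[3:7, 3:7] = 0.1
        out = op.step(state, 10.0)
        assert np.array_equal(out.c, state.c)
        assert np.array_equal(out.c_b, state.c_b)


class TestMembraneAdvection:
    def test_pulse_centroid_moves_at_drainage_speed(self, params):
        grid = pc.make_calibration_domain(4e-3, 2e-3, 25e-6)
        p = params.replace(t_inject=0.0)
        op = TransportOperator(grid, p, custom_case(diffusion=1, drainage=1),
                               injection_mode="no_flux")
        state = FieldState.zeros(grid)
        i0, j0 = 20, grid.ny // 2
        state.c_b[i0, j0] = 1.0
        dt = op.stable_dt()
        n = int(120.0 / dt)
        for _ in range(n):
            state = op.step(state, dt)
        X, _ = grid.cell_centers()
        centroid = float((state.c_b * X).sum() / state.c_b.sum())
        expected = X[i0, j0] + p.u_b * n * dt
        assert abs(centroid - expected) <= grid.dx

    def test_drainage_accumulates_at_downstream_boundary(self, params):
        """Advected tracer piles up in the last interior cell; none is lost."""
        grid = pc.make_calibration_domain(1e-3, 0.5e-3, 50e-6)
        p = params.replace(t_inject=0.0)
        op = TransportOperator(grid, p, custom_case(diffusion=1, drainage=1),
                               injection_mode="no_flux")
        state = FieldState.zeros(grid)
        state.c_b[2, grid.ny // 2] = 1.0
        total0 = state.c_b.sum()
        dt = op.stable_dt()
        for _ in range(int(600.0 / dt)):  # long enough to cross the domain
            state = op.step(state, dt)
        assert state.c_b.sum() == pytest.approx(total0, rel=1e-12)
        assert np.argmax(state.c_b.sum(axis=1)) == grid.nx - 1


class TestHeatKernel:
    def test_point_release_matches_gaussian(self, params, heat_kernel_run):
        """Diffusion-only spread of a point release follows the 2D heat kernel."""
        grid, result, t, moles = heat_kernel_run
        state = result.state_at(t)
        X, Y = grid.cell_centers()
        r2 = (X - grid.needle_tip[0]) ** 2 + (Y - grid.needle_tip[1]) ** 2
        D = params.D_star
        exact = moles / (4 * np.pi * D * t) * np.exp(-r2 / (4 * D * t))
        err = np.linalg.norm(state.c - exact) / np.linalg.norm(exact)
        assert err < 0.02

    def test_mass_is_conserved_through_the_run(self, heat_kernel_run):
        _, result, _, moles = heat_kernel_run
        assert np.allclose(result.moles_ecs, moles, rtol=1e-10)


class TestInjection:
    def test_inflow_held_at_c0_during_injection(self, params):
        grid = pc.make_calibration_domain(2e-3, 2e-3, 50e-6, source="point")
        op = TransportOperator(grid, params, pc.build_case("A1"))
        state = FieldState.zeros(grid)
        op.apply_injection(state)
        for _ in range(10):
            state = op.step(state, 1.0)
        assert state.c[grid.inflow] == pytest.approx(params.c0)

    def test_post_injection_modes(self, params):
        grid = pc.make_calibration_domain(2e-3, 2e-3, 50e-6, source="point")
        for mode, check in (("dirichlet_zero", lambda v: v == 0.0),
                            ("no_flux", lambda v: v > 0.0)):
            op = TransportOperator(grid, params.replace(t_inject=5.0),
                                   pc.build_case("A1"), injection_mode=mode)
            state = FieldState.zeros(grid)
            op.apply_injection(state)
            for _ in range(20):
                state = op.step(state, 1.0)
            assert check(float(state.c[grid.inflow][0])), mode

    def test_injection_convection_flag_runs_stably(self, params):
        """The optional injection-driven radial flow stays stable and keeps
        at least as much early spread as the flow-free run."""
        grid = pc.make_calibration_domain(2e-3, 2e-3, 50e-6, source="point")
        base = pc.run_simulation(pc.build_case("A1"), grid, params,
                                 t_total=120.0, record_dt=60.0)
        pushed = pc.run_simulation(pc.build_case("A1"), grid,
                                   params.replace(u_inject=4.0e-6),
                                   t_total=120.0, record_dt=60.0)
        assert np.all(pushed.dist_ecs >= base.dist_ecs - 1e-12)
        assert pushed.snapshots[-1].c.min() >= -1e-12 * params.c0

    def test_zero_duration_injection_stays_dark(self, params):
        grid = pc.make_calibration_domain(2e-3, 2e-3, 50e-6, source="point")
        res = pc.run_simulation(pc.build_case("A1"), grid,
                                params.replace(t_inject=0.0),
                                t_total=100.0, record_dt=50.0)
        assert np.all(res.dist_combined == 0.0)
        assert res.snapshots[-1].c.max() == 0.0


class TestStabilityAndSafety:
    def test_nonnegativity_under_stable_dt(self, params):
        grid = pc.make_calibration_domain(2e-3, 2e-3, 50e-6, source="point")
        res = pc.run_simulation(pc.build_case("C1"), grid, params,
                                t_total=300.0, record_dt=100.0)
        for snap in res.snapshots:
            assert snap.c.min() >= -1e-12 * params.c0
            assert snap.c_b.min() >= -1e-12 * params.c0

    def test_divergence_raises_with_time(self, params):
        grid = pc.make_calibration_domain(2e-3, 2e-3, 50e-6, source="point")
        op = TransportOperator(grid, params, pc.build_case("A1"))
        state = FieldState.zeros(grid)
        op.apply_injection(state)
        unstable_dt = 100 * op.stable_dt()
        with pytest.raises(SolverDivergenceError) as err:
            for _ in range(50):
                state = op.step(state, unstable_dt)
        assert err.value.t is not None

    def test_mass_ledger_conserved_per_step(self, params):
        """No injection + no-flux tip: total moles constant to 1e-10 per step."""
        grid = pc.make_calibration_domain(4e-3, 2e-3, 50e-6)
        p = params.replace(t_inject=0.0)
        op = TransportOperator(grid, p, custom_case(diffusion=1, drainage=1, uptake=1),
                               injection_mode="no_flux")
        state = FieldState.zeros(grid)
        state.c[20:40, 15:25] = 0.2
        prev = sum(op.moles(state))
        for _ in range(100):
            state = op.step(state, 1.0)
            tot = sum(op.moles(state))
            assert abs(tot - prev) <= 1e-10 * prev
            prev = tot


class TestCoronalRuns:
    def test_deterministic_repeat(self, params):
        grid = pc.make_calibration_domain(2e-3, 2e-3, 50e-6, source="point")
        r1 = pc.run_simulation(pc.build_case("C1"), grid, params,
                               t_total=200.0, record_dt=50.0)
        r2 = pc.run_simulation(pc.build_case("C1"), grid, params,
                               t_total=200.0, record_dt=50.0)
        assert np.array_equal(r1.dist_combined, r2.dist_combined)
        assert np.array_equal(r1.snapshots[-1].c, r2.snapshots[-1].c)

    def test_membrane_mass_nondecreasing_in_full_model(self, coronal_run):
        """Uptake feeds the membrane before the front drains to the boundary."""
        res = coronal_run("C1")
        reach = pc.first_passage_time(res.times, res.dist_membrane, 2.4e-3)
        early = res.times <= (reach if reach else res.times[-1])
        dm = np.diff(res.moles_membrane[early])
        assert np.all(dm >= -1e-15)

    def test_drainage_speed_orders_detection_distance(self, coronal_run):
        """At 5 min after injection the spread is non-decreasing in u_b."""
        d = {cid: interp_distance(coronal_run(cid), 420.0)
             for cid in ("A1", "C2", "C1")}  # u_b multipliers 0, 0.5, 1
        assert d["A1"] <= d["C2"] + 1e-12
        assert d["C2"] <= d["C1"] + 1e-12

    def test_grid_convergence_of_detection_distance(self, params):
        """Halving dx moves the 7-min diffusion-only distance by < 3 %."""
        dist = {}
        for dx in (25e-6, 12.5e-6):
            grid = pc.make_slice(pc.coronal_like_spec(dx=dx))
            res = pc.run_simulation(pc.build_case("A1"), grid, params,
                                    t_total=420.0, record_dt=420.0)
            dist[dx] = res.dist_ecs[-1]
        assert abs(dist[12.5e-6] - dist[25e-6]) / dist[25e-6] < 0.03
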