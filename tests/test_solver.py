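"""Pontryagin machinery: Hamiltonian, adjoint, pointwise control rules,
and small end-to-end sweep solves."""

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from myelopt.cost import CostSpec, evaluate_cost
from myelopt.model import SystemState
from myelopt.simulate import ControlSignal, TimeGrid, integrate
from myelopt.solver import (
    SolverConfig,
    adjoint_rhs,
    adjoint_roundtrip_residual,
    hamiltonian,
    solve,
    stationary_control_quadratic,
    switching_function,
)


def _random_point(rng):
    state = SystemState(*rng.uniform(0.05, 0.8, size=3))
    adjoint = tuple(rng.uniform(-2.0, 2.0, size=3))
    u = float(rng.uniform(0.0, 1.0))
    return state, adjoint, u


class TestHamiltonian:
    def test_zero_adjoint_reduces_to_running_cost(self, default_params, rng):
        spec = CostSpec.linear()
        for _ in range(10):
            state, _, u = _random_point(rng)
            h = hamiltonian(state, (0.0, 0.0, 0.0), u, default_params, spec)
            assert h == pytest.approx(u + state.P + state.N, rel=1e-12)

    def test_origin_picks_up_influx_only(self, default_params):
        h = hamiltonian(
            SystemState(0, 0, 0), (2.0, 0.0, 0.0), 0.0, default_params, CostSpec.linear()
        )
        assert h == pytest.approx(2.0 * 0.1008, abs=1e-15)

    @pytest.mark.parametrize("spec", [CostSpec.linear(), CostSpec.quadratic(),
                                      CostSpec.mixed(0.7, 0.3, 1.0, 0.5)])
    def test_du_derivative_matches_finite_difference(self, default_params, rng, spec):
        h_step = 1e-6
        for _ in range(100):
            state, adjoint, u = _random_point(rng)
            u = max(u, 2 * h_step)
            fd = (
                hamiltonian(state, adjoint, u + h_step, default_params, spec)
                - hamiltonian(state, adjoint, u - h_step, default_params, spec)
            ) / (2 * h_step)
            analytic = (
                spec.w_u_lin
                + 2 * spec.w_u_quad * u
                - adjoint[0] * default_params.mu_Au * state.A
                - adjoint[1] * (default_params.mu_Pu + default_params.delta_Pu) * state.P
                + adjoint[2] * default_params.delta_Pu * state.P
            )
            assert fd == pytest.approx(analytic, abs=1e-8)


class TestAdjointRhs:
    @pytest.mark.parametrize("spec", [CostSpec.linear(), CostSpec.quadratic()])
    def test_matches_finite_differences_of_H(self, default_params, rng, spec):
        h_step = 1e-5
        for _ in range(200):
            state, adjoint, u = _random_point(rng)
            out = adjoint_rhs(state, adjoint, u, default_params, spec)
            x = state.to_array()
            for j, name in enumerate(("A", "P", "N")):
                xp, xm = x.copy(), x.copy()
                xp[j] += h_step
                xm[j] -= h_step
                dH = (
                    hamiltonian(SystemState(*xp), adjoint, u, default_params, spec)
                    - hamiltonian(SystemState(*xm), adjoint, u, default_params, spec)
                ) / (2 * h_step)
                assert out[j] == pytest.approx(-dH, abs=1e-7), name

    def test_zero_adjoint_linear_cost(self, default_params):
        out = adjoint_rhs(
            SystemState(0.3, 0.2, 0.1), (0, 0, 0), 0.5, default_params, CostSpec.linear()
        )
        # lambda' = -dL/dx with L = u + P + N
        assert out == pytest.approx((0.0, -1.0, -1.0), abs=1e-15)


class TestPointwiseControlRules:
    def test_stationary_control_reference_value(self, default_params):
        u = stationary_control_quadratic(
            SystemState(0.3, 0.2, 0.01), (0.1, 2.0, 1.0), default_params, CostSpec.quadratic()
        )
        # (0.1*0.1*0.3 + 2*(1+0.2)*0.2 - 1*0.2*0.2) / 2
        assert u == pytest.approx(0.2215, abs=1e-12)

    def test_stationary_control_matches_numeric_minimiser(self, default_params, rng):
        spec = CostSpec.quadratic()
        for _ in range(20):
            state, adjoint, _ = _random_point(rng)
            u_star = stationary_control_quadratic(state, adjoint, default_params, spec)
            res = minimize_scalar(
                lambda v: hamiltonian(state, adjoint, v, default_params, spec),
                bounds=(0.0, 10.0),
                method="bounded",
                options={"xatol": 1e-10},
            )
            assert u_star == pytest.approx(res.x, abs=1e-6)

    def test_zero_adjoint_gives_zero_control(self, default_params):
        u = stationary_control_quadratic(
            SystemState(0.5, 0.3, 0.1), (0, 0, 0), default_params, CostSpec.quadratic()
        )
        assert u == 0.0

    def test_negative_bracket_clips_to_zero(self, default_params):
        u = stationary_control_quadratic(
            SystemState(0.3, 0.2, 0.01), (-1.0, -2.0, 0.0), default_params, CostSpec.quadratic()
        )
        assert u == 0.0

    def test_stationary_requires_quadratic_weight(self, default_params):
        with pytest.raises(ValueError):
            stationary_control_quadratic(
                SystemState(0.3, 0.2, 0.01), (0, 0, 0), default_params, CostSpec.linear()
            )

    def test_switching_function_reference_value(self, default_params):
        phi = switching_function(
            SystemState(0.3, 0.2, 0.01), (0.1, 2.0, 1.0), default_params, CostSpec.linear()
        )
        assert phi == pytest.approx(0.557, abs=1e-12)
        assert phi > 0  # candidate control is 0

    def test_switching_function_zero_adjoint(self, default_params):
        phi = switching_function(
            SystemState(0.3, 0.2, 0.01), (0, 0, 0), default_params, CostSpec.linear()
        )
        assert phi == 1.0

    def test_switching_matches_H_finite_difference(self, default_params, rng):
        spec = CostSpec.linear()
        h_step = 1e-6
        for _ in range(20):
            state, adjoint, u = _random_point(rng)
            phi = switching_function(state, adjoint, default_params, spec)
            fd = (
                hamiltonian(state, adjoint, u + h_step, default_params, spec)
                - hamiltonian(state, adjoint, u - h_step, default_params, spec)
            ) / (2 * h_step)
            assert phi == pytest.approx(fd, abs=1e-8)


@pytest.fixture(scope="module")
def quad_solution(default_params, cancer_eq):
    spec = CostSpec.quadratic()
    config = SolverConfig(grid=TimeGrid(0.0, 20.0, 0.01))
    return solve(default_params, cancer_eq, spec, config), spec


@pytest.fixture(scope="module")
def null_linear_solution(null_params, null_cancer_eq):
    spec = CostSpec.linear()
    config = SolverConfig(grid=TimeGrid(0.0, 100.0, 0.01))
    return solve(null_params, null_cancer_eq, spec, config), spec


class TestQuadraticSolve:
    def test_converged_with_small_stationarity_residual(self, quad_solution):
        result, _ = quad_solution
        assert result.converged
        u = result.control.values
        interior = (u > 1e-6) & (u < 10.0 - 1e-6)
        assert np.max(np.abs(result.diagnostics.stationarity[interior])) < 1e-3

    def test_cap_never_active(self, quad_solution):
        result, _ = quad_solution
        assert not result.u_cap_active

    def test_beats_constant_baselines(self, quad_solution, default_params, cancer_eq):
        result, spec = quad_solution
        grid = result.control.grid
        best_constant = np.inf
        for level in np.linspace(0.0, 1.0, 21):
            control = ControlSignal.constant(grid, level, upper=10.0)
            traj = integrate(default_params, cancer_eq, control)
            best_constant = min(best_constant, evaluate_cost(traj, control, spec).total)
        assert result.cost.total <= best_constant + 1e-9

    def test_control_decreasing_from_high_start(self, quad_solution):
        result, _ = quad_solution
        u = result.control.values
        assert u[0] > 0.2
        assert np.all(np.diff(u) <= 1e-6)

    def test_adjoint_roundtrip(self, quad_solution, default_params):
        result, spec = quad_solution
        assert adjoint_roundtrip_residual(result, default_params, spec) < 1e-6

    def test_terminal_adjoint_is_zero(self, quad_solution):
        result, _ = quad_solution
        assert np.all(result.adjoint[-1] == 0.0)

    def test_gradient_consistency_at_random_nodes(
        self, quad_solution, default_params, cancer_eq, rng
    ):
        """Perturbing one node of the converged control changes J by
        eps * dH/du * dt + O(eps^2)."""
        result, spec = quad_solution
        grid = result.control.grid
        eps = 1e-3
        nodes = rng.integers(grid.n_nodes // 10, 9 * grid.n_nodes // 10, size=10)
        for node in nodes:
            g_adj = result.diagnostics.stationarity[node] * grid.dt
            u_pert = result.control.values.copy()
            u_pert[node] += eps
            control = result.control.with_values(u_pert)
            traj = integrate(default_params, cancer_eq, control)
            dj = evaluate_cost(traj, control, spec).total - result.cost.total
            assert dj == pytest.approx(eps * g_adj, abs=2 * eps**2 + 1e-10)

    def test_history_shape(self, quad_solution):
        result, _ = quad_solution
        assert result.history.shape == (result.iterations, 2)

    def test_cost_consistent_with_evaluate_cost(
        self, quad_solution, default_params, cancer_eq
    ):
        result, spec = quad_solution
        traj = integrate(default_params, cancer_eq, result.control)
        assert np.max(np.abs(traj.states - result.trajectory.states)) < 1e-12
        again = evaluate_cost(traj, result.control, spec)
        assert again.total == pytest.approx(result.cost.total, rel=1e-12)


class TestNullNLinearSolve:
    def test_bang_bang_structure(self, null_linear_solution):
        result, _ = null_linear_solution
        assert result.converged
        u = result.control.values
        at_bound = (u < 1e-3) | (u > 1.0 - 1e-3)
        # everything at a bound except (at most) a thin switching neighbourhood
        off_bound_time = float(np.sum(~at_bound)) * result.control.grid.dt
        assert off_bound_time <= 1.0

    def test_single_switch(self, null_linear_solution):
        result, _ = null_linear_solution
        u = result.control.values
        on = u > 0.5
        switches = np.sum(np.abs(np.diff(on.astype(int))))
        assert switches == 1
        assert on[0] and not on[-1]

    def test_switching_function_single_sign_change(self, null_linear_solution):
        result, _ = null_linear_solution
        phi = result.diagnostics.switching
        signs = np.sign(phi[np.abs(phi) > 1e-4])
        changes = np.sum(np.abs(np.diff(signs)) > 0)
        assert changes == 1

    def test_bang_violation_negligible(self, null_linear_solution):
        result, _ = null_linear_solution
        assert result.diagnostics.bang_violation_fraction < 0.01

    def test_beats_constant_baselines(self, null_linear_solution, null_params, null_cancer_eq):
        result, spec = null_linear_solution
        grid = result.control.grid
        for level in np.linspace(0.0, 1.0, 21):
            control = ControlSignal.constant(grid, level)
            traj = integrate(null_params, null_cancer_eq, control)
            assert result.cost.total <= evaluate_cost(traj, control, spec).total + 1e-9


class TestSolverConfigValidation:
    def test_omega_bounds(self):
        grid = TimeGrid(0.0, 1.0, 0.1)
        with pytest.raises(ValueError):
            SolverConfig(grid=grid, omega=0.0)
        with pytest.raises(ValueError):
            SolverConfig(grid=grid, omega=1.5)

    def test_step_bounds(self):
        grid = TimeGrid(0.0, 1.0, 0.1)
        with pytest.raises(ValueError):
            SolverConfig(grid=grid, step_init=0.0)
        with pytest.raises(ValueError):
            SolverConfig(grid=grid, step_shrink=1.2)

    def test_bad_u_init_shape_rejected(self, default_params, cancer_eq):
        config = SolverConfig(grid=TimeGrid(0.0, 1.0, 0.1), u_init=np.zeros(5))
        with pytest.raises(ValueError):
            solve(default_params, cancer_eq, CostSpec.linear(), config)

    def test_warm_start_accepted(self, default_params, cancer_eq):
        grid = TimeGrid(0.0, 5.0, 0.05)
        config = SolverConfig(grid=grid, u_init=0.5, max_iterations=50)
        result = solve(default_params, cancer_eq, CostSpec.quadratic(), config)
        assert result.iterations <= 50


class TestMixedCostSolve:
    def test_mixed_form_converges_between_pure_forms(self, default_params, cancer_eq):
        # a convex mixed cost solves through the stationary-candidate path
        spec = CostSpec.mixed(0.5, 0.5, 1.0, 0.5, u_max=2.0)
        grid = TimeGrid(0.0, 10.0, 0.02)
        result = solve(default_params, cancer_eq, spec, SolverConfig(grid=grid))
        assert result.converged
        u = result.control.values
        assert float(u.min()) >= 0.0
        assert float(u.max()) <= 2.0
        # PMP consistency: wherever the gradient points inward, the control
        # sits at (or decays toward) the corresponding bound
        dH = result.diagnostics.stationarity
        assert np.all(u[dH > 1e-3] < 1e-3)
        assert np.all(u[dH < -1e-3] > 2.0 - 1e-3)
        active = (u > 1e-2) & (u < 2.0 - 1e-2)
        if np.any(active):
            assert np.max(np.abs(dH[active])) < 1e-2
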