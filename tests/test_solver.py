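"""Pontryagin machinery: Hamiltonian, adjoint, projected stationarity, BVP."""

import numpy as np
import pytest

import celldose as cd
from celldose.solver import SolverSettings

from _oracles import fd_gradient, random_structured_model, riccati_lqr


def _random_problem(rng, wide_bounds=True):
    model = random_structured_model(rng)
    n, m = model.n, model.m
    R = np.diag(rng.uniform(0.5, 2.0, m))
    cost = cd.CostSpec(M=np.zeros((n, n)), Q=np.eye(n), R=R, T=1.0)
    bounds = (np.full(m, -50.0), np.full(m, 50.0)) if wide_bounds else None
    return cd.OCProblem(model, cost, np.abs(rng.uniform(0, 1, n)), control_bounds=bounds)


class TestHamiltonian:
    def test_zero_state_zero_control(self, two_pop_problem):
        assert cd.hamiltonian(two_pop_problem, [0, 0], [0, 0], [1, 1]) == 0.0

    def test_zero_adjoint_is_pure_running_cost(self, two_pop_problem, rng):
        x, u = rng.uniform(0, 2, 2), rng.uniform(0, 1, 2)
        expected = 0.5 * (x @ x + 0.1 * u @ u)
        assert cd.hamiltonian(two_pop_problem, x, u, [0, 0]) == pytest.approx(expected)

    def test_two_population_hand_value(self, two_pop_problem):
        # running cost 1 plus lam . rhs = 1 + (1, 1).(1, 0) = 2
        assert cd.hamiltonian(two_pop_problem, [1, 1], [0, 0], [1, 1]) == pytest.approx(2.0)


class TestAdjointRhs:
    def test_reduces_to_linear_transpose_term(self, rng):
        model = random_structured_model(rng)
        n, m = model.n, model.m
        cost = cd.CostSpec(np.zeros((n, n)), np.zeros((n, n)), np.eye(m), 1.0)
        prob = cd.OCProblem(model, cost, np.ones(n))
        lam = rng.uniform(-1, 1, n)
        np.testing.assert_allclose(
            cd.adjoint_rhs(prob, np.zeros(n), np.zeros(m), lam),
            -model.A.T @ lam,
            atol=1e-14,
        )

    def test_zero_adjoint_leaves_state_penalty(self, two_pop_problem, rng):
        x = rng.uniform(0, 2, 2)
        np.testing.assert_allclose(
            cd.adjoint_rhs(two_pop_problem, x, [0.3, 0.7], [0, 0]), -x
        )

    def test_matches_finite_differences(self, rng):
        for _ in range(20):
            prob = _random_problem(rng)
            n, m = prob.model.n, prob.model.m
            x, u = rng.uniform(0, 2, n), rng.uniform(0, 1, m)
            lam = rng.uniform(-1, 1, n)
            fd = -fd_gradient(lambda z: cd.hamiltonian(prob, z, u, lam), x)
            got = cd.adjoint_rhs(prob, x, u, lam)
            np.testing.assert_allclose(got, fd, rtol=1e-6, atol=1e-8)


class TestStationaryControl:
    def test_no_coupling_gives_zero(self, rng):
        n, m = 2, 2
        model = cd.ControlledODEModel(
            np.eye(n), np.zeros((n, m)), np.zeros((n, n, m)), np.zeros((n, n, m, m))
        )
        prob = cd.OCProblem(model, cd.CostSpec(np.zeros((n, n)), np.eye(n), np.eye(m), 1.0), np.ones(n))
        u, cond = cd.stationary_control(prob, rng.uniform(0, 1, n), rng.uniform(-1, 1, n))
        np.testing.assert_array_equal(u, 0.0)
        assert cond == pytest.approx(1.0)

    def test_pure_additive_control_recovers_lqr_law(self, rng):
        n, m = 2, 2
        B = rng.uniform(-1, 1, (n, m))
        R = np.diag([0.5, 2.0])
        model = cd.ControlledODEModel(np.eye(n), B, np.zeros((n, n, m)), np.zeros((n, n, m, m)))
        prob = cd.OCProblem(
            model,
            cd.CostSpec(np.zeros((n, n)), np.eye(n), R, 1.0),
            np.ones(n),
            control_bounds=(np.full(m, -100.0), np.full(m, 100.0)),
        )
        lam = rng.uniform(-1, 1, n)
        u, _ = cd.stationary_control(prob, np.zeros(n), lam)
        np.testing.assert_allclose(u, -np.linalg.solve(R, B.T @ lam), atol=1e-12)

    def test_matches_dense_grid_search_on_box(self, two_pop_problem, rng):
        # oracle: minimise H over [0,1]^2 on a fine grid
        for _ in range(5):
            x, lam = rng.uniform(0, 2, 2), rng.uniform(-2, 2, 2)
            ustar, _ = cd.stationary_control(two_pop_problem, x, lam)
            gg = np.linspace(0, 1, 101)
            H = np.array(
                [[cd.hamiltonian(two_pop_problem, x, [a, b], lam) for b in gg] for a in gg]
            )
            ia, ib = np.unravel_index(np.argmin(H), H.shape)
            assert abs(ustar[0] - gg[ia]) < 1e-2 + 1e-9
            assert abs(ustar[1] - gg[ib]) < 1e-2 + 1e-9

    def test_singular_hessian_raises(self):
        # one source state, two drugs, synergy tuned so G = R + x lam Dsym is singular
        n, m = 1, 2
        D = np.zeros((n, n, m, m))
        D[0, 0, 1, 0] = 1.0
        model = cd.ControlledODEModel(np.zeros((n, n)), np.zeros((n, m)), np.zeros((n, n, m)), D)
        prob = cd.OCProblem(model, cd.CostSpec(np.zeros((n, n)), np.eye(n), np.eye(m), 1.0), np.ones(n))
        with pytest.raises(cd.SingularOptimality):
            cd.stationary_control(prob, np.array([1.0]), np.array([1.0]))


class TestSolve:
    def test_no_state_cost_means_no_treatment(self, two_pop_model):
        cost = cd.CostSpec(np.zeros((2, 2)), np.zeros((2, 2)), 0.1 * np.eye(2), 3.0)
        prob = cd.OCProblem(two_pop_model, cost, np.ones(2))
        sol = cd.solve(prob)
        np.testing.assert_allclose(sol.lam, 0.0, atol=1e-8)
        np.testing.assert_allclose(sol.u, 0.0, atol=1e-8)
        free = cd.simulate_forward(two_pop_model, np.ones(2), np.zeros(2), 3.0, t_eval=sol.t)
        np.testing.assert_allclose(sol.x, free.x, atol=1e-3)

    def test_default_two_population_stationarity(self, two_pop_solution):
        sol = two_pop_solution
        assert sol.converged
        assert sol.stationarity_residual < 1e-3
        assert np.all(sol.u >= 0) and np.all(sol.u <= 1)

    def test_transversality(self, two_pop_solution, two_pop_problem):
        M = two_pop_problem.cost.M
        np.testing.assert_allclose(
            two_pop_solution.lam[-1], M @ two_pop_solution.x[-1], atol=1e-8
        )

    def test_terminal_penalty_transversality(self, two_pop_model):
        M = np.diag([2.0, 1.0])
        cost = cd.CostSpec(M, np.eye(2), 0.1 * np.eye(2), 3.0)
        prob = cd.OCProblem(two_pop_model, cost, np.ones(2))
        sol = cd.solve(prob)
        np.testing.assert_allclose(sol.lam[-1], M @ sol.x[-1], atol=1e-6)

    def test_lqr_matches_riccati_oracle(self, rng):
        n = m = 2
        A = rng.uniform(-1, 1, (n, n))
        A -= (np.max(np.linalg.eigvals(A).real) + 0.3) * np.eye(n)
        B = rng.uniform(-1, 1, (n, m))
        R = np.diag(rng.uniform(0.5, 2.0, m))
        model = cd.ControlledODEModel(A, B, np.zeros((n, n, m)), np.zeros((n, n, m, m)))
        prob = cd.OCProblem(
            model,
            cd.CostSpec(np.zeros((n, n)), np.eye(n), R, 3.0),
            rng.uniform(0.5, 1.5, n),
            control_bounds=(np.full(m, -100.0), np.full(m, 100.0)),
        )
        sol = cd.solve(prob, SolverSettings(tol=1e-6))
        P_of_t, x_of_t = riccati_lqr(A, B, np.eye(n), R, np.zeros((n, n)), 3.0, prob.x0)
        for i, t in enumerate(sol.t):
            xr = x_of_t(t)
            ur = -np.linalg.solve(R, B.T @ P_of_t(t) @ xr)
            np.testing.assert_allclose(sol.x[i], xr, atol=1e-4)
            np.testing.assert_allclose(sol.u[i], ur, atol=1e-4)

    def test_nonconvergence_raises_with_diagnostics(self, two_pop_problem):
        starved = SolverSettings(max_nodes=8, initial_nodes=5)
        with pytest.raises(cd.ConvergenceError) as err:
            cd.solve(two_pop_problem, starved)
        assert "attempts" in err.value.diagnostics


class TestSimulateForward:
    def test_equilibrium_stays_constant(self):
        model = cd.ControlledODEModel(
            np.zeros((2, 2)), np.zeros((2, 1)), np.zeros((2, 2, 1)), np.zeros((2, 2, 1, 1))
        )
        traj = cd.simulate_forward(model, [1.0, 2.0], np.zeros(1), 5.0)
        np.testing.assert_allclose(
            traj.x, np.broadcast_to([1.0, 2.0], traj.x.shape), atol=1e-12
        )

    def test_scalar_exponential_growth(self):
        a = -0.7
        model = cd.ControlledODEModel(np.array([[a]]), np.zeros((1, 1)), np.zeros((1, 1, 1)), np.zeros((1, 1, 1, 1)))
        traj = cd.simulate_forward(model, [2.0], np.zeros(1), 3.0)
        np.testing.assert_allclose(traj.x[-1, 0], 2.0 * np.exp(a * 3.0), rtol=1e-6)

    def test_replaying_optimal_control_reproduces_state(
        self, two_pop_problem, two_pop_solution
    ):
        traj = cd.simulate_forward(
            two_pop_problem.model, two_pop_problem.x0, two_pop_solution, 7.0,
            t_eval=two_pop_solution.t,
        )
        np.testing.assert_allclose(traj.x, two_pop_solution.x, atol=5e-3)

    def test_constant_control_shape_checked(self, two_pop_model):
        with pytest.raises(cd.ModelValidationError):
            cd.simulate_forward(two_pop_model, [1, 1], np.zeros(3), 1.0)


class TestCostSpecValidation:
    def test_asymmetric_Q_rejected(self):
        with pytest.raises(cd.ModelValidationError, match="symmetric"):
            cd.CostSpec(np.zeros((2, 2)), np.array([[1.0, 0.2], [0.0, 1.0]]), np.eye(2), 1.0)

    def test_indefinite_R_rejected(self):
        with pytest.raises(cd.ModelValidationError, match="positive definite"):
            cd.CostSpec(np.zeros((2, 2)), np.eye(2), np.diag([1.0, -0.1]), 1.0)

    def test_time_varying_penalties_accepted(self, two_pop_model):
        cost = cd.CostSpec(
            np.zeros((2, 2)), lambda t: np.eye(2), lambda t: 0.1 * np.eye(2), 2.0
        )
        prob = cd.OCProblem(two_pop_model, cost, np.ones(2))
        sol = cd.solve(prob, SolverSettings(initial_nodes=21))
        assert sol.converged
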