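"""Legendre-Gauss-Lobatto machinery and the transcription."""

import numpy as np
import pytest
from scipy.optimize import minimize

from glyopt import collocation as cl


class TestNodesWeights:
    def test_two_point_rule(self):
        nodes, w = cl.lgl_nodes_weights(1)
        np.testing.assert_allclose(nodes, [-1.0, 1.0])
        np.testing.assert_allclose(w, [1.0, 1.0])

    def test_three_point_rule_closed_form(self):
        nodes, w = cl.lgl_nodes_weights(2)
        np.testing.assert_allclose(nodes, [-1.0, 0.0, 1.0], atol=1e-14)
        np.testing.assert_allclose(w, [1 / 3, 4 / 3, 1 / 3], rtol=1e-13)

    @pytest.mark.parametrize("N", list(range(1, 41)))
    def test_weights_sum_to_interval_length(self, N):
        _, w = cl.lgl_nodes_weights(N)
        assert w.sum() == pytest.approx(2.0, rel=1e-12)

    @pytest.mark.parametrize("N", [2, 5, 9, 16])
    def test_quadrature_exact_to_degree_2N_minus_1(self, N):
        nodes, w = cl.lgl_nodes_weights(N)
        for deg in range(2 * N):
            exact = (1 - (-1) ** (deg + 1)) / (deg + 1)
            assert np.dot(w, nodes ** deg) == pytest.approx(exact, abs=1e-11)

    def test_invalid_order(self):
        with pytest.raises(ValueError):
            cl.lgl_nodes_weights(0)


class TestDifferentiationMatrix:
    def test_two_node_closed_form(self):
        D = cl.differentiation_matrix(np.array([-1.0, 1.0]))
        np.testing.assert_allclose(D, [[-0.5, 0.5], [-0.5, 0.5]], atol=1e-14)

    @pytest.mark.parametrize("N", [1, 3, 8, 20])
    def test_annihilates_constants(self, N):
        g = cl.CollocationGrid(N)
        assert np.abs(g.D @ np.ones(N + 1)).max() < 1e-10

    @pytest.mark.parametrize("N,deg", [(2, 2), (5, 4), (10, 7)])
    def test_exact_on_polynomials_up_to_nodal_degree(self, N, deg):
        g = cl.CollocationGrid(N)
        vals = g.nodes ** deg
        deriv = deg * g.nodes ** (deg - 1)
        np.testing.assert_allclose(g.D @ vals, deriv, atol=1e-9)

    def test_duplicate_nodes_rejected(self):
        with pytest.raises(ValueError):
            cl.differentiation_matrix(np.array([0.0, 0.0, 1.0]))


class TestMapTime:
    @pytest.mark.parametrize("tau,expect", [(-1.0, 0.0), (1.0, 300.0),
                                            (0.0, 150.0)])
    def test_affine_endpoints_and_midpoint(self, tau, expect):
        assert cl.map_time(tau, 0.0, 300.0) == pytest.approx(expect)

    def test_reversed_horizon_rejected(self):
        with pytest.raises(ValueError):
            cl.map_time(0.0, 10.0, 10.0)


def _toy_phase(N, tf=1.0):
    def dyn(X, U):
        return U[0:1]

    def dyn_jac(X, U):
        return np.zeros((X.shape[1], 1, 1)), np.ones((1, 1))

    return cl.PhaseSpec(0.0, tf, N, dyn, dyn_jac)


def _solve_toy(N):
    """min int (x - t)^2 dt, xdot = u, x(0) = 0: optimum u* = 1, J* = 0."""
    ph = _toy_phase(N)
    tt = ph.times

    def integrand(X, U):
        return (X[0] - tt) ** 2

    def integrand_grad(X, U):
        return 2 * (X[0] - tt)[None, :], np.zeros_like(U)

    nlp = cl.transcribe([ph], 1, 1, integrand, integrand_grad,
                        np.array([0.0]),
                        (np.array([-10.0]), np.array([10.0])),
                        (np.array([-5.0]), np.array([5.0])))
    z0 = nlp.pack([(np.zeros((1, N + 1)), np.zeros((1, N + 1)))])
    res = minimize(nlp.objective, z0, jac=nlp.objective_grad,
                   bounds=nlp.bounds(),
                   constraints=[{"type": "eq", "fun": nlp.eq_constraints,
                                 "jac": nlp.eq_jacobian}],
                   method="SLSQP", options={"maxiter": 300, "ftol": 1e-14})
    return nlp, res


class TestTranscription:
    def test_zero_dynamics_only_constant_feasible(self):
        ph = _toy_phase(6)

        def dyn(X, U):
            return np.zeros_like(X)

        def dyn_jac(X, U):
            return np.zeros((X.shape[1], 1, 1)), np.zeros((1, 1))

        ph.dynamics, ph.dynamics_jac = dyn, dyn_jac
        Xs = cl.solve_defects([ph], np.array([3.5]),
                              [np.zeros((1, 7))])
        np.testing.assert_allclose(Xs[0], 3.5, rtol=1e-10)

    def test_linear_quadratic_toy_recovers_analytic_optimum(self):
        nlp, res = _solve_toy(10)
        assert res.success
        assert res.fun == pytest.approx(0.0, abs=1e-10)
        (X, U), = nlp.unpack(res.x)
        # interior controls recover u* = 1 (the first node's control is
        # free: it enters neither a defect nor the optimal quadrature)
        np.testing.assert_allclose(U[0, 1:], 1.0, atol=1e-5)

    def test_toy_objective_error_decreases_with_order(self):
        errs = [abs(_solve_toy(N)[1].fun) for N in (4, 8, 12)]
        assert errs[0] >= errs[1] >= errs[2] - 1e-12

    def test_quadrature_of_constant_integrand(self):
        ph = _toy_phase(7, tf=300.0)

        def integrand(X, U):
            return np.full(X.shape[1], 2.5)

        nlp = cl.transcribe([ph], 1, 1, integrand, lambda X, U: (0 * X, 0 * U),
                            np.array([0.0]),
                            (np.array([-1.0]), np.array([1.0])),
                            (np.array([0.0]), np.array([1.0])))
        z = nlp.pack([(np.zeros((1, 8)), np.zeros((1, 8)))])
        assert nlp.objective(z) == pytest.approx(300.0 * 2.5, rel=1e-12)


class TestDefectOracle:
    def test_collocated_states_match_integrator(self, patient, x_fasting,
                                                meal):
        """For a fixed basal control, the defect-feasible trajectory agrees
        with adaptive integration to < 0.5 mg/dL in glucose (order 40)."""
        from glyopt import model as gm
        from glyopt.dosing import DosingSchedule
        from glyopt.params import IX, NSTATES

        jump = np.zeros(NSTATES)
        jump[IX["Qsto1"]] = meal.milligrams

        def mk(t0, t1, N, D, j=None):
            dyn = lambda X, U: gm.rhs(X, U[0], 0.0, patient, meal_D=D)
            djac = lambda X, U: (gm.rhs_jacobian(X, 0, 0, patient,
                                                 meal_D=D)[0], None)
            return cl.PhaseSpec(t0, t1, N, dyn, djac, jump=j)

        phases = [mk(0, 60, 40, 0.0), mk(60, 300, 40, meal.milligrams, jump)]
        controls = [np.full((1, 41), 0.0024)] * 2
        Xs = cl.solve_defects(phases, x_fasting, controls)
        sched = DosingSchedule.constant(0, 300, 0.0024)
        traj = gm.simulate(patient, x_fasting, sched, meal, (0, 300))
        for ph, X in zip(phases, Xs):
            Gc = X[IX["Gp"]] / patient["VG"]
            shift = 1e-9 if ph.jump is not None else 0.0
            Gi = np.interp(ph.times + shift, traj.t, traj.glucose)
            assert np.abs(Gc - Gi).max() < 0.5
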