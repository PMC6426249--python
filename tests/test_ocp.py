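"""Optimal-control problems: objective, pulses, solution invariants."""

import numpy as np
import pytest

from glyopt.dosing import MealScenario
from glyopt.metrics import bgi, bgi_minimizer
from glyopt.ocp import (GlucoseRegulationOCP, OCPConfig, detect_pulses,
                        objective_integrand)


class TestObjectiveIntegrand:
    def test_vanishes_at_target_with_zero_control(self):
        cfg = OCPConfig(p=1, alpha_p=10.0, alpha_I=1.0, u_b=0.0)
        assert objective_integrand(bgi_minimizer(), 0.0, 0.0, cfg) == \
            pytest.approx(0.0, abs=1e-18)

    def test_minimum_fuel_value_at_low_glucose(self):
        cfg = OCPConfig(p=1, alpha_p=10.0, alpha_I=1.0)
        expect = 10.0 * bgi(70.0) + 1.0
        assert objective_integrand(70.0, 1.0, 0.0, cfg) == \
            pytest.approx(expect, rel=1e-12)
        assert expect == pytest.approx(78.6, abs=0.3)

    def test_minimum_energy_control_term_is_quadratic(self):
        cfg = OCPConfig(p=2, alpha_p=0.0, alpha_I=1.0)
        base = objective_integrand(112.51, 1.0, 0.0, cfg)
        doubled = objective_integrand(112.51, 2.0, 0.0, cfg)
        assert doubled == pytest.approx(4.0 * base, rel=1e-12)

    def test_glucagon_term_only_in_dual_mode(self):
        mono = OCPConfig(p=1, dual_hormone=False)
        dual = OCPConfig(p=1, dual_hormone=True, alpha_G=1.0)
        g_mono = objective_integrand(112.51, 0.0024, 0.1, mono)
        g_dual = objective_integrand(112.51, 0.0024, 0.1, dual)
        assert g_dual > g_mono

    def test_invalid_exponent_rejected(self):
        with pytest.raises(ValueError):
            OCPConfig(p=3)


class TestDetectPulses:
    def test_rectangle(self):
        t = np.linspace(0, 300, 3001)
        u = np.where((t >= 100) & (t <= 102), 1.0, 0.0)
        pulses = detect_pulses(t, u, baseline=0.0, min_prominence=0.1)
        assert len(pulses) == 1
        assert 100 <= pulses[0]["peak_time"] <= 102
        assert pulses[0]["amount"] == pytest.approx(2.0, abs=0.15)

    def test_two_rectangles_ordered_by_amount(self):
        t = np.linspace(0, 300, 3001)
        u = np.where((t >= 50) & (t <= 51), 1.0, 0.0) \
            + np.where((t >= 200) & (t <= 205), 1.0, 0.0)
        pulses = detect_pulses(t, u, min_prominence=0.1)
        assert len(pulses) == 2
        assert pulses[0]["amount"] > pulses[1]["amount"]
        assert pulses[0]["peak_time"] == pytest.approx(202.5, abs=0.5)

    def test_flat_trace_yields_no_pulses(self):
        t = np.linspace(0, 300, 301)
        assert detect_pulses(t, np.full_like(t, 0.0024),
                             baseline=0.0024, min_prominence=0.024) == []


class TestBuild:
    def test_meal_must_be_inside_horizon(self, patient):
        with pytest.raises(ValueError):
            GlucoseRegulationOCP(patient, MealScenario(70, 400.0), OCPConfig())

    def test_mono_problem_has_no_glucagon_variables(self, patient, meal):
        nlp = GlucoseRegulationOCP(patient, meal,
                                   OCPConfig(dual_hormone=False)).build()
        assert nlp.nu == 1

    def test_insulin_lower_bound_is_basal_rate(self, patient, meal):
        nlp = GlucoseRegulationOCP(patient, meal, OCPConfig()).build()
        assert nlp.uL[0] == pytest.approx(0.0024)
        assert nlp.uU[0] == pytest.approx(15.0)

    def test_inconsistent_bounds_rejected(self):
        with pytest.raises(ValueError):
            OCPConfig(G_L=200.0, G_U=100.0)


class TestNoMealProblem:
    def test_optimum_is_basal_rate_throughout(self, patient):
        """With no meal, staying at the fasting steady state under the
        minimum allowed infusion is optimal: u = u_b, Delta ~ 0."""
        cfg = OCPConfig(p=1, seg_pre=4, seg_post=8, maxiter=100)
        sol = GlucoseRegulationOCP(patient, MealScenario(0.0, 60.0),
                                   cfg).solve()
        assert sol.success
        np.testing.assert_allclose(sol.node_uI, 0.0024, atol=1e-4)
        assert sol.metrics.delta < 1.0
        assert sol.metrics.g_min == pytest.approx(bgi_minimizer(), abs=0.5)


class TestSolutionInvariants:
    def test_mono_remf_constraints_hold(self, mono_remf):
        cfg = mono_remf.config
        G = mono_remf.node_glucose
        assert G.min() >= cfg.G_L - 1e-6
        assert G.max() <= cfg.G_U + 1e-6
        assert np.all(mono_remf.node_uI >= cfg.u_b - 1e-10)
        assert np.all(mono_remf.node_uI <= cfg.uI_U + 1e-10)
        assert mono_remf.metrics.phi_I <= cfg.phi_I_U + 1e-6
        assert mono_remf.constraint_violation < 1e-6

    def test_dual_remf_dose_caps(self, dual_remf):
        cfg = dual_remf.config
        assert dual_remf.metrics.phi_I <= cfg.phi_I_U + 1e-4
        assert dual_remf.metrics.phi_G <= cfg.phi_G_U + 1e-6
        assert np.all(dual_remf.node_uG >= -1e-12)
        assert np.all(dual_remf.node_uG <= cfg.uG_U + 1e-10)

    @pytest.mark.parametrize("fixture", ["mono_remf", "dual_remf",
                                         "mono_reme", "dual_reme"])
    def test_objective_consistent_with_resimulation(self, fixture, request):
        """The solver-reported J matches re-quadrature of the integrand on
        the re-simulated trajectory to < 0.5%."""
        sol = request.getfixturevalue(fixture)
        assert sol.success
        requad = sol.requadrature_objective()
        assert abs(sol.objective - requad) / max(requad, 1.0) < 5e-3

    @pytest.mark.parametrize("fixture", ["mono_remf", "dual_remf"])
    def test_simulation_cross_check(self, fixture, request):
        """Integrating the model under the optimized control reproduces the
        collocation glucose trajectory to < 1 mg/dL at the nodes."""
        sol = request.getfixturevalue(fixture)
        tr = sol.trajectory
        G_sim = np.interp(sol.node_t + 1e-9, tr.t, tr.glucose)
        assert np.abs(G_sim - sol.node_glucose).max() < 1.0

    def test_reme_controls_are_smoother_than_remf(self, mono_remf,
                                                  mono_reme):
        """Quadratic control cost spreads delivery: the peak infusion rate
        of the minimum-energy optimum is below the minimum-fuel one."""
        assert mono_reme.node_uI.max() <= mono_remf.node_uI.max() + 1e-9

    def test_summary_mentions_key_metrics(self, mono_remf):
        text = mono_remf.summary()
        assert "Delta" in text and "phi_I" in text and "pulse" in text
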