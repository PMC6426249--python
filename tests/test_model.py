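"""The 17-state model: right-hand side, Jacobian, calibration, simulation."""

import numpy as np
import pytest

from glyopt import model as gm
from glyopt.dosing import BolusEvent, DosingSchedule, MealScenario
from glyopt.params import (IX, NSTATES, STATE_NAMES, MissingParameterError,
                           PatientParameters)

#: a physiologically plausible state scale used to draw random states
_SCALE = np.array([240, 180, 5, 4, 8, 8, 2e4, 2e4, 2e4, 5, 19, 93, 1,
                   50, 50, 100, 100], dtype=float)


def _random_states(rng, n):
    return np.abs(rng.normal(1.0, 0.5, (n, NSTATES))) * _SCALE


class TestRhs:
    def test_basal_state_is_steady(self, patient):
        dx = gm.rhs(patient.basal_state, 0.0, 0.0, patient)
        assert np.max(np.abs(dx)) < 1e-9

    def test_glucose_output_is_gp_over_vg(self, patient):
        x = patient.basal_state.copy()
        x[IX["Gp"]] = 200.0
        assert gm.glucose_output(x, patient) == pytest.approx(
            200.0 / patient["VG"])

    def test_analytic_jacobian_matches_finite_differences(self, patient):
        rng = np.random.default_rng(0)
        for x in _random_states(rng, 5):
            Jx, Ju = gm.rhs_jacobian(x, 0.1, 0.01, patient, meal_D=7e4)
            f0 = gm.rhs(x, 0.1, 0.01, patient, meal_D=7e4)
            for j in range(NSTATES):
                h = 1e-6 * max(abs(x[j]), 1.0)
                xp = x.copy()
                xp[j] += h
                fd = (gm.rhs(xp, 0.1, 0.01, patient, meal_D=7e4) - f0) / h
                assert np.abs(Jx[:, j] - fd).max() < 1e-4 * (1 + np.abs(fd).max())
            # control Jacobian: inputs enter the depots linearly
            fI = gm.rhs(x, 1.1, 0.01, patient, meal_D=7e4)
            assert fI[IX["Isc1"]] - f0[IX["Isc1"]] == pytest.approx(
                Ju[IX["Isc1"], 0], rel=1e-9)
            fG = gm.rhs(x, 0.1, 0.02, patient, meal_D=7e4)
            assert fG[IX["Hsc1"]] - f0[IX["Hsc1"]] == pytest.approx(
                0.01 * Ju[IX["Hsc1"], 1], rel=1e-9)

    def test_vectorized_rhs_matches_loop(self, patient):
        rng = np.random.default_rng(1)
        X = _random_states(rng, 8).T
        uI = np.linspace(0, 2, 8)
        uG = np.linspace(0, 0.1, 8)
        batch = gm.rhs(X, uI, uG, patient, meal_D=7e4)
        for k in range(8):
            single = gm.rhs(X[:, k], uI[k], uG[k], patient, meal_D=7e4)
            np.testing.assert_allclose(batch[:, k], single, rtol=1e-12)

    def test_smooth_max_within_one_percent_beyond_five_widths(self):
        """Each smoothed rectifier agrees with its hard counterpart to
        better than 1% of the argument's magnitude once the argument is
        at least 5 smoothing widths from the switch point."""
        rng = np.random.default_rng(7)
        for w in (0.01, 0.05, 0.1, 0.5, 1.0):
            z = rng.uniform(-200 * w, 200 * w, 500)
            z = z[np.abs(z) >= 5.001 * w]
            err = np.abs(gm.smooth_max(z, w) - np.maximum(z, 0.0))
            assert np.all(err <= 0.01 * np.abs(z))

    def test_smoothed_rhs_close_to_piecewise_away_from_switches(self,
                                                                patient):
        p = patient.values
        rng = np.random.default_rng(2)
        checked = 0
        for x in _random_states(rng, 100):
            egp_lin = (p["kp1"] - p["kp2"] * x[IX["Gp"]]
                       - p["kp3"] * x[IX["XL"]] + p["xi"] * x[IX["XH"]])
            inner = (p["sigma"] * (p["Gth"] - x[IX["Gp"]] / p["VG"])
                     / (x[IX["Ip"]] / p["VI"] + 1.0) + p["SRHb"])
            dGp = gm.rhs(x, 0.0, 0.0, patient, meal_D=7e4)[IX["Gp"]]
            near = (abs(x[IX["Gp"]] - p["ke2"]) < 5 * p["w_renal"]
                    or abs(egp_lin) < 5 * p["w_egp"]
                    or abs(x[IX["H"]] - p["Hb"]) < 5 * p["w_xh"]
                    or abs(inner) < 5 * p["w_srhs"]
                    or abs(p["delta"] * dGp / p["VG"]) < 5 * p["w_srhd"])
            if near:
                continue
            sm = gm.rhs(x, 0.05, 0.01, patient, meal_D=7e4, smoothed=True)
            hard = gm.rhs(x, 0.05, 0.01, patient, meal_D=7e4, smoothed=False)
            assert np.max(np.abs(sm - hard) - 0.01 * (1 + np.abs(hard))) < 0
            checked += 1
        assert checked > 50

    def test_nonfinite_state_rejected(self, patient):
        x = patient.basal_state.copy()
        x[0] = np.nan
        with pytest.raises(ValueError):
            gm.rhs(x, 0.0, 0.0, patient)

    def test_missing_parameter_named_in_error(self, patient):
        vals = dict(patient.values)
        del vals["Vmx"]
        with pytest.raises(MissingParameterError, match="Vmx"):
            PatientParameters(vals)


class TestCalibration:
    def test_basal_hold_300min(self, patient):
        """Calibrated basal state holds G = G_b to < 0.5 mg/dL for 300 min
        with zero exogenous input and no meal."""
        sched = DosingSchedule.constant(0, 300, 0.0)
        traj = gm.simulate(patient, patient.basal_state, sched, None, (0, 300))
        assert np.max(np.abs(traj.glucose - patient.basal_glucose)) < 0.5

    def test_calibrate_basal_hits_target(self, patient):
        recal = gm.calibrate_basal(patient, 120.0)
        assert gm.glucose_output(recal.basal_state, recal) == pytest.approx(120.0)
        assert np.max(np.abs(gm.rhs(recal.basal_state, 0, 0, recal))) < 1e-9

    def test_steady_state_glucose_decreases_with_insulin(self, patient):
        rates = [0.0, 0.001, 0.0024, 0.004]
        G = [gm.glucose_output(
            gm.steady_state_under_constant_insulin(patient, u), patient)
            for u in rates]
        assert all(a > b for a, b in zip(G[:-1], G[1:]))

    def test_fasting_under_basal_reaches_target(self, patient, x_fasting):
        from glyopt.metrics import bgi_minimizer

        assert gm.glucose_output(x_fasting, patient) == pytest.approx(
            bgi_minimizer(), abs=0.1)


class TestSimulate:
    def test_meal_impulse_exact_jump(self, patient, x_fasting, meal):
        sched = DosingSchedule.constant(0, 300, 0.0024)
        traj = gm.simulate(patient, x_fasting, sched, meal, (0, 300))
        at = np.where(np.isclose(traj.t, meal.time))[0]
        assert at.size == 2          # tau^- and tau^+ both on the grid
        pre, post = traj.states[:, at[0]], traj.states[:, at[1]]
        assert post[IX["Qsto1"]] - pre[IX["Qsto1"]] == pytest.approx(
            meal.milligrams)
        others = [k for k in range(NSTATES) if k != IX["Qsto1"]]
        np.testing.assert_allclose(post[others], pre[others],
                                   rtol=1e-9, atol=1e-9)

    def test_glucose_rises_after_meal_under_basal_only(self, patient,
                                                       x_fasting, meal):
        sched = DosingSchedule.constant(0, 300, 0.0024)
        traj = gm.simulate(patient, x_fasting, sched, meal, (0, 300))
        G0 = traj.glucose[0]
        assert traj.glucose[traj.t > 90].max() > G0 + 50

    def test_adaptive_vs_fixed_step_oracle(self, patient, x_fasting, meal):
        """Adaptive integration agrees with an independent fixed-step RK4
        integration to < 0.1 mg/dL in glucose over the whole horizon."""
        sched = DosingSchedule.constant(0, 300, 0.0024)
        traj = gm.simulate(patient, x_fasting, sched, meal, (0, 300))
        # independent RK4 oracle at h = 0.05 min with the meal jump
        h = 0.05
        x = x_fasting.copy()
        ts, Gs = [0.0], [x[IX["Gp"]] / patient["VG"]]
        t = 0.0
        meal_D = 0.0
        f = lambda y: gm.rhs(y, 0.0024, 0.0, patient, meal_D=meal_D)
        while t < 300.0 - 1e-9:
            if np.isclose(t, meal.time):
                x = x.copy()
                x[IX["Qsto1"]] += meal.milligrams
                meal_D = meal.milligrams
            k1 = f(x)
            k2 = f(x + 0.5 * h * k1)
            k3 = f(x + 0.5 * h * k2)
            k4 = f(x + h * k3)
            x = x + (h / 6) * (k1 + 2 * k2 + 2 * k3 + k4)
            t += h
            ts.append(t)
            Gs.append(x[IX["Gp"]] / patient["VG"])
        G_adapt = np.interp(np.array(ts) + 1e-9, traj.t, traj.glucose)
        assert np.max(np.abs(G_adapt - np.array(Gs))) < 0.1

    def test_states_stay_nonnegative(self, patient, x_fasting, meal):
        sched = DosingSchedule(0, 300, basal_insulin=0.0024,
                               boluses=(BolusEvent("insulin", 10.0, 30.0),
                                        BolusEvent("glucagon", 0.4, 150.0)))
        traj = gm.simulate(patient, x_fasting, sched, meal, (0, 300))
        assert traj.states.min() > -1e-8

    def test_schedule_must_cover_horizon(self, patient, x_fasting):
        sched = DosingSchedule.constant(0, 100, 0.0024)
        with pytest.raises(ValueError):
            gm.simulate(patient, x_fasting, sched, None, (0, 300))

    def test_trajectory_dataframe_columns(self, patient, x_fasting):
        sched = DosingSchedule.constant(0, 50, 0.0024)
        traj = gm.simulate(patient, x_fasting, sched, None, (0, 50))
        df = traj.to_dataframe()
        assert list(df.columns) == (["time_min"] + list(STATE_NAMES)
                                    + ["G_mgdl", "uI_Umin", "uG_mgmin"])
        np.testing.assert_allclose(df["G_mgdl"],
                                   df["Gp"] / patient["VG"], rtol=1e-12)
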