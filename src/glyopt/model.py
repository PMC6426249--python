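"""The 17-state glucose-insulin-glucagon model of a Type 1 diabetes patient.

The model couples five subsystems: plasma/tissue glucose kinetics with
endogenous glucose production (EGP), renal excretion and insulin-dependent
utilization; a three-compartment oral glucose absorption chain (solid
stomach, liquid stomach, gut) with a nonlinear gastric emptying rate;
plasma/liver insulin kinetics fed by a two-compartment subcutaneous
depot; glucagon secretion, plasma kinetics and delayed action on EGP fed
by a two-compartment subcutaneous depot; and remote insulin action.  In
Type 1 diabetes there is no endogenous insulin secretion, so all insulin
enters through the subcutaneous route.

Exogenous inputs are the insulin infusion rate u_I (U/min, converted to
pmol/kg/min via 6000 pmol per insulin Unit and the body weight), the
glucagon infusion rate u_G (mg/min, converted to ng/L/min via the
glucagon distribution volume), and the meal, an impulse of D mg of
glucose into the solid stomach compartment at the meal time.

Four right-hand-side terms are non-differentiable in the original model
(renal excretion threshold, the two glucagon secretion rectifiers, the
EGP floor).  Each ``max(z, 0)`` is replaced by the smooth approximation
``(z + sqrt(z^2 + w^2)) / 2`` with a per-term width ``w``, so that the
right-hand side is continuously differentiable for the optimizer; the
widths are parameters and default to values far below the physiological
scale of each term.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq, root

from glyopt.dosing import DosingSchedule, MealScenario
from glyopt.params import IX, NSTATES, STATE_NAMES, PatientParameters


class SimulationError(RuntimeError):
    pass


class CalibrationError(RuntimeError):
    pass


# ---------------------------------------------------------------------
# smooth max
# ---------------------------------------------------------------------

def smooth_max(z, w):
    """Smooth approximation of max(z, 0) with width w (exact as w -> 0)."""
    return 0.5 * (z + np.sqrt(z * z + w * w))


def smooth_max_d(z, w):
    """Derivative of :func:`smooth_max` with respect to z."""
    return 0.5 * (1.0 + z / np.sqrt(z * z + w * w))


def _gastric_emptying(qsto, D, p):
    """Gastric emptying rate k_empt(Q_sto) for a meal of D mg.

    The rate is k_max for an empty or full stomach and dips to k_min in
    between; the transition points scale with the meal size.  With no
    meal (D <= 0) the stomach is empty and the rate is the constant k_max.
    """
    kmax, kmin, b, c = p["kmax"], p["kmin"], p["b"], p["c"]
    if D <= 0.0:
        return np.broadcast_to(kmax, np.shape(qsto)).astype(float), np.zeros(np.shape(qsto))
    alpha = 5.0 / (2.0 * D * (1.0 - b))
    beta = 5.0 / (2.0 * D * c)
    ta = np.tanh(alpha * (qsto - b * D))
    tb = np.tanh(beta * (qsto - c * D))
    half = 0.5 * (kmax - kmin)
    k = kmin + half * (ta - tb + 2.0)
    dk = half * (alpha * (1.0 - ta * ta) - beta * (1.0 - tb * tb))
    return k, dk


# ---------------------------------------------------------------------
# right-hand side
# ---------------------------------------------------------------------

def rhs(x, uI, uG, params: PatientParameters, meal_D: float = 0.0,
        smoothed: bool = True):
    """Time derivative of the 17 states (per minute).

    Parameters
    ----------
    x
        State vector, shape (17,) or (17, M) for vectorized evaluation.
    uI, uG
        Insulin (U/min) and glucagon (mg/min) infusion rates, scalars or
        length-M arrays.
    params
        Complete patient parameters.
    meal_D
        Size (mg) of the meal currently transiting the gut; sets the
        gastric emptying profile.  Zero when no meal has been consumed.
    smoothed
        If True (default) use the smooth replacements of the four
        non-differentiable terms; if False use the hard piecewise forms.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite state passed to rhs")
    p = params.values
    mx = smooth_max if smoothed else (lambda z, w: np.maximum(z, 0.0))

    Gp, Gt = x[IX["Gp"]], x[IX["Gt"]]
    Il, Ip = x[IX["Il"]], x[IX["Ip"]]
    I1, XL = x[IX["I1"]], x[IX["XL"]]
    Qsto1, Qsto2, Qgut = x[IX["Qsto1"]], x[IX["Qsto2"]], x[IX["Qgut"]]
    X = x[IX["X"]]
    SRHs, H, XH = x[IX["SRHs"]], x[IX["H"]], x[IX["XH"]]
    Isc1, Isc2 = x[IX["Isc1"]], x[IX["Isc2"]]
    Hsc1, Hsc2 = x[IX["Hsc1"]], x[IX["Hsc2"]]

    G = Gp / p["VG"]
    I = Ip / p["VI"]

    egp_lin = p["kp1"] - p["kp2"] * Gp - p["kp3"] * XL + p["xi"] * XH
    EGP = mx(egp_lin, p["w_egp"])
    E = p["ke1"] * mx(Gp - p["ke2"], p["w_renal"])
    Ra = p["f"] * p["kabs"] * Qgut / p["BW"]
    Uid = (p["Vm0"] + p["Vmx"] * X) * Gt / (p["Km0"] + Gt)

    kempt, _ = _gastric_emptying(Qsto1 + Qsto2, meal_D, p)

    dx = np.empty_like(x)
    dGp = EGP + Ra - p["Fcns"] - E - p["k1"] * Gp + p["k2"] * Gt
    dx[IX["Gp"]] = dGp
    dx[IX["Gt"]] = -Uid + p["k1"] * Gp - p["k2"] * Gt
    dx[IX["Il"]] = -(p["m1"] + p["m3"]) * Il + p["m2"] * Ip
    dx[IX["Ip"]] = (-(p["m2"] + p["m4"]) * Ip + p["m1"] * Il
                    + p["ka1"] * Isc1 + p["ka2"] * Isc2)
    dx[IX["I1"]] = -p["ki"] * (I1 - I)
    dx[IX["XL"]] = -p["ki"] * (XL - I1)
    dx[IX["Qsto1"]] = -p["kgri"] * Qsto1
    dx[IX["Qsto2"]] = p["kgri"] * Qsto1 - kempt * Qsto2
    dx[IX["Qgut"]] = kempt * Qsto2 - p["kabs"] * Qgut
    dx[IX["X"]] = -p["p2U"] * X + p["p2U"] * (I - p["Ib"])
    srhs_target = mx(p["sigma"] * (p["Gth"] - G) / (I + 1.0) + p["SRHb"],
                     p["w_srhs"])
    dx[IX["SRHs"]] = -p["rho"] * (SRHs - srhs_target)
    SRHd = mx(-p["delta"] * dGp / p["VG"], p["w_srhd"])
    RaH = p["kh3"] * Hsc2
    dx[IX["H"]] = -p["n"] * H + SRHs + SRHd + RaH
    dx[IX["XH"]] = -p["kH"] * (XH - mx(H - p["Hb"], p["w_xh"]))
    dx[IX["Isc1"]] = -(p["kd"] + p["ka1"]) * Isc1 + np.asarray(uI) * p["U_to_pmol"] / p["BW"]
    dx[IX["Isc2"]] = p["kd"] * Isc1 - p["ka2"] * Isc2
    dx[IX["Hsc1"]] = (-(p["kh1"] + p["kh2"]) * Hsc1
                      + np.asarray(uG) * p["mg_to_ng"] / (p["VH"] * p["BW"]))
    dx[IX["Hsc2"]] = p["kh1"] * Hsc1 - p["kh3"] * Hsc2
    return dx


def rhs_jacobian(x, uI, uG, params: PatientParameters, meal_D: float = 0.0):
    """Analytic Jacobians of the smoothed right-hand side.

    Returns ``(Jx, Ju)`` with ``Jx`` of shape (17, 17) (or (M, 17, 17)
    when ``x`` has shape (17, M)) and ``Ju`` of shape (17, 2) for the
    inputs (u_I, u_G).  ``Ju`` is constant in the state and controls.
    """
    x = np.asarray(x, dtype=float)
    p = params.values
    vec = x.ndim == 2
    M = x.shape[1] if vec else 1
    xs = x if vec else x[:, None]

    Gp, Gt = xs[IX["Gp"]], xs[IX["Gt"]]
    Ip, XL, XH = xs[IX["Ip"]], xs[IX["XL"]], xs[IX["XH"]]
    Qsto2 = xs[IX["Qsto2"]]
    X = xs[IX["X"]]
    H = xs[IX["H"]]
    qsto = xs[IX["Qsto1"]] + Qsto2
    G = Gp / p["VG"]
    I = Ip / p["VI"]

    J = np.zeros((M, NSTATES, NSTATES))

    egp_lin = p["kp1"] - p["kp2"] * Gp - p["kp3"] * XL + p["xi"] * XH
    segp = smooth_max_d(egp_lin, p["w_egp"])
    sren = smooth_max_d(Gp - p["ke2"], p["w_renal"])
    kempt, dkempt = _gastric_emptying(qsto, meal_D, p)

    i = IX
    # row Gp:  EGP + Ra - Fcns - E - k1 Gp + k2 Gt
    dGp_dGp = -segp * p["kp2"] - p["ke1"] * sren - p["k1"]
    dGp_dGt = np.full(M, p["k2"])
    dGp_dXL = -segp * p["kp3"]
    dGp_dXH = segp * p["xi"]
    dGp_dQgut = np.full(M, p["f"] * p["kabs"] / p["BW"])
    J[:, i["Gp"], i["Gp"]] = dGp_dGp
    J[:, i["Gp"], i["Gt"]] = dGp_dGt
    J[:, i["Gp"], i["XL"]] = dGp_dXL
    J[:, i["Gp"], i["XH"]] = dGp_dXH
    J[:, i["Gp"], i["Qgut"]] = dGp_dQgut

    # row Gt
    J[:, i["Gt"], i["Gp"]] = p["k1"]
    J[:, i["Gt"], i["Gt"]] = (-p["k2"]
                              - (p["Vm0"] + p["Vmx"] * X) * p["Km0"]
                              / (p["Km0"] + Gt) ** 2)
    J[:, i["Gt"], i["X"]] = -p["Vmx"] * Gt / (p["Km0"] + Gt)

    # rows Il, Ip
    J[:, i["Il"], i["Il"]] = -(p["m1"] + p["m3"])
    J[:, i["Il"], i["Ip"]] = p["m2"]
    J[:, i["Ip"], i["Ip"]] = -(p["m2"] + p["m4"])
    J[:, i["Ip"], i["Il"]] = p["m1"]
    J[:, i["Ip"], i["Isc1"]] = p["ka1"]
    J[:, i["Ip"], i["Isc2"]] = p["ka2"]

    # delayed insulin signal chain
    J[:, i["I1"], i["I1"]] = -p["ki"]
    J[:, i["I1"], i["Ip"]] = p["ki"] / p["VI"]
    J[:, i["XL"], i["XL"]] = -p["ki"]
    J[:, i["XL"], i["I1"]] = p["ki"]

    # meal chain
    J[:, i["Qsto1"], i["Qsto1"]] = -p["kgri"]
    J[:, i["Qsto2"], i["Qsto1"]] = p["kgri"] - Qsto2 * dkempt
    J[:, i["Qsto2"], i["Qsto2"]] = -kempt - Qsto2 * dkempt
    J[:, i["Qgut"], i["Qsto1"]] = Qsto2 * dkempt
    J[:, i["Qgut"], i["Qsto2"]] = kempt + Qsto2 * dkempt
    J[:, i["Qgut"], i["Qgut"]] = -p["kabs"]

    # remote insulin action
    J[:, i["X"], i["X"]] = -p["p2U"]
    J[:, i["X"], i["Ip"]] = p["p2U"] / p["VI"]

    # static glucagon secretion
    inner = p["sigma"] * (p["Gth"] - G) / (I + 1.0) + p["SRHb"]
    ssrhs = smooth_max_d(inner, p["w_srhs"])
    J[:, i["SRHs"], i["SRHs"]] = -p["rho"]
    J[:, i["SRHs"], i["Gp"]] = p["rho"] * ssrhs * (-p["sigma"] / ((I + 1.0) * p["VG"]))
    J[:, i["SRHs"], i["Ip"]] = p["rho"] * ssrhs * (
        -p["sigma"] * (p["Gth"] - G) / ((I + 1.0) ** 2 * p["VI"]))

    # plasma glucagon; SRHd chains through dGp/dt
    dGp_row = {"Gp": dGp_dGp, "Gt": dGp_dGt, "XL": dGp_dXL,
               "XH": dGp_dXH, "Qgut": dGp_dQgut}
    egp_full = smooth_max(egp_lin, p["w_egp"])
    E = p["ke1"] * smooth_max(Gp - p["ke2"], p["w_renal"])
    Ra = p["f"] * p["kabs"] * xs[IX["Qgut"]] / p["BW"]
    dGp_val = egp_full + Ra - p["Fcns"] - E - p["k1"] * Gp + p["k2"] * Gt
    ssrhd = smooth_max_d(-p["delta"] * dGp_val / p["VG"], p["w_srhd"])
    J[:, i["H"], i["H"]] = -p["n"]
    J[:, i["H"], i["SRHs"]] = 1.0
    J[:, i["H"], i["Hsc2"]] = p["kh3"]
    for name, dval in dGp_row.items():
        J[:, i["H"], i[name]] += ssrhd * (-p["delta"] / p["VG"]) * dval

    # delayed glucagon action
    J[:, i["XH"], i["XH"]] = -p["kH"]
    J[:, i["XH"], i["H"]] = p["kH"] * smooth_max_d(H - p["Hb"], p["w_xh"])

    # subcutaneous depots
    J[:, i["Isc1"], i["Isc1"]] = -(p["kd"] + p["ka1"])
    J[:, i["Isc2"], i["Isc1"]] = p["kd"]
    J[:, i["Isc2"], i["Isc2"]] = -p["ka2"]
    J[:, i["Hsc1"], i["Hsc1"]] = -(p["kh1"] + p["kh2"])
    J[:, i["Hsc2"], i["Hsc1"]] = p["kh1"]
    J[:, i["Hsc2"], i["Hsc2"]] = -p["kh3"]

    Ju = np.zeros((NSTATES, 2))
    Ju[i["Isc1"], 0] = p["U_to_pmol"] / p["BW"]
    Ju[i["Hsc1"], 1] = p["mg_to_ng"] / (p["VH"] * p["BW"])

    if not vec:
        return J[0], Ju
    return J, Ju


def glucose_output(x, params: PatientParameters):
    """Blood glucose concentration G = G_p / V_G (mg/dL)."""
    return np.asarray(x)[IX["Gp"]] / params["VG"]


# ---------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------

@dataclass
class Trajectory:
    """A simulated patient trajectory on a monotone time grid."""

    t: np.ndarray                  # min
    states: np.ndarray             # (17, len(t))
    params: PatientParameters
    schedule: DosingSchedule
    meal: MealScenario | None = None

    @property
    def glucose(self) -> np.ndarray:
        """G(t) = Gp(t)/VG in mg/dL."""
        return self.states[IX["Gp"]] / self.params["VG"]

    def to_dataframe(self):
        import pandas as pd

        cols = {"time_min": self.t}
        for k, name in enumerate(STATE_NAMES):
            cols[name] = self.states[k]
        cols["G_mgdl"] = self.glucose
        cols["uI_Umin"] = self.schedule.insulin_rate(self.t)
        cols["uG_mgmin"] = self.schedule.glucagon_rate(self.t)
        return pd.DataFrame(cols)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def simulate(params: PatientParameters, x0, schedule: DosingSchedule,
             meal: MealScenario | None, t_span, rtol: float = 1e-8,
             atol: float = 1e-10, grid_step: float = 0.5,
             method: str = "LSODA") -> Trajectory:
    """Integrate the smoothed model under a dosing schedule and a meal.

    The meal impulse is realized exactly: integration stops at the meal
    time, D mg is added to the solid stomach compartment, and integration
    restarts; the output grid contains both the pre- and post-meal state.
    Integration also restarts at every schedule discontinuity.
    """
    t0, tf = float(t_span[0]), float(t_span[1])
    x0 = np.asarray(x0, dtype=float)
    if not np.all(np.isfinite(x0)):
        raise ValueError("non-finite initial state")
    if schedule.t0 > t0 + 1e-9 or schedule.tf < tf - 1e-9:
        raise ValueError("schedule does not cover the simulation horizon")
    if meal is not None and not (t0 <= meal.time <= tf):
        raise ValueError("meal time outside the simulation horizon")

    breaks = set(schedule.breakpoints().tolist()) | {t0, tf}
    if meal is not None:
        breaks.add(meal.time)
    breaks = np.array(sorted(b for b in breaks if t0 <= b <= tf))

    ts, xs = [], []
    x = x0.copy()
    meal_D = 0.0
    for ta, tb in zip(breaks[:-1], breaks[1:]):
        if meal is not None and np.isclose(ta, meal.time):
            ts.append(ta)          # tau_D^- then tau_D^+
            xs.append(x.copy())
            x = x.copy()
            x[IX["Qsto1"]] += meal.milligrams
            meal_D = meal.milligrams
        n = max(int(np.ceil((tb - ta) / grid_step)), 2)
        t_eval = np.linspace(ta, tb, n + 1)

        def f(t, y, _D=meal_D):
            return rhs(y, schedule.insulin_rate(t), schedule.glucagon_rate(t),
                       params, meal_D=_D)

        def jac(t, y, _D=meal_D):
            return rhs_jacobian(y, 0.0, 0.0, params, meal_D=_D)[0]

        kwargs = {"rtol": rtol, "atol": atol, "t_eval": t_eval}
        if method in ("LSODA", "BDF", "Radau"):
            kwargs["jac"] = jac
        sol = solve_ivp(f, (ta, tb), x, method=method, **kwargs)
        if not sol.success:
            raise SimulationError(f"integration failed near t={sol.t[-1]:.2f}: "
                                  f"{sol.message}")
        ts.append(sol.t[:-1] if tb < tf else sol.t)
        xs.append(sol.y[:, :-1] if tb < tf else sol.y)
        x = sol.y[:, -1].copy()

    t = np.concatenate([np.atleast_1d(a) for a in ts])
    states = np.column_stack([np.atleast_2d(a.T).T if a.ndim == 1 else a
                              for a in (s if s.ndim == 2 else s[:, None] for s in xs)])
    return Trajectory(t=t, states=states, params=params, schedule=schedule,
                      meal=meal)


# ---------------------------------------------------------------------
# steady states and calibration
# ---------------------------------------------------------------------

def _steady_state(params: PatientParameters, uI: float, uG: float = 0.0,
                  x_init: np.ndarray | None = None,
                  burn_in: float = 2000.0) -> np.ndarray:
    """Asymptotic state under constant inputs, by burn-in then root polish."""
    if x_init is None:
        x_init = _analytic_basal_guess(params)
    sched = DosingSchedule.constant(0.0, burn_in, uI, uG)
    traj = simulate(params, x_init, sched, None, (0.0, burn_in),
                    rtol=1e-8, atol=1e-10, grid_step=burn_in / 50)
    x_guess = traj.states[:, -1]
    sol = root(lambda y: rhs(y, uI, uG, params),
               x_guess, jac=lambda y: rhs_jacobian(y, uI, uG, params)[0],
               method="hybr", tol=1e-12)
    resid = np.max(np.abs(rhs(sol.x, uI, uG, params)))
    if resid > 1e-8:
        raise CalibrationError(
            f"no steady state found (residual {resid:.3g})")
    return sol.x


def _analytic_basal_guess(params: PatientParameters) -> np.ndarray:
    """Closed-form zero-input basal state used to seed root finding."""
    p = params.values
    x = np.zeros(NSTATES)
    Gb = params.basal_glucose if params.basal_glucose is not None else 130.0
    Gp = Gb * p["VG"]
    # tissue glucose from the glucose-flux balance at X = 0
    def bal(gt):
        return p["k1"] * Gp - p["k2"] * gt - p["Vm0"] * gt / (p["Km0"] + gt)
    gt_hi = p["k1"] * Gp / p["k2"]
    x[IX["Gp"]] = Gp
    x[IX["Gt"]] = brentq(bal, 1e-6, gt_hi) if bal(gt_hi) < 0 else gt_hi
    x[IX["SRHs"]] = p["SRHb"]
    x[IX["H"]] = p["Hb"]
    return x


def steady_state_under_constant_insulin(params: PatientParameters,
                                        u_const: float) -> np.ndarray:
    """Asymptotic no-meal state under u_I = u_const, u_G = 0."""
    if u_const < 0:
        raise ValueError("insulin rate must be nonnegative")
    x0 = params.basal_state if params.basal_state is not None else None
    return _steady_state(params, u_const, 0.0, x_init=x0)


def calibrate_basal(params: PatientParameters, G_b: float
                    ) -> PatientParameters:
    """Calibrate the EGP scale so the zero-input steady state sits at G_b.

    The basal condition fixes plasma glucose at ``G_b * VG``; the single
    free production parameter kp1 is solved jointly with the remaining 16
    basal states so that the smoothed right-hand side vanishes exactly.
    Returns a copy of ``params`` with kp1, ``basal_glucose`` and
    ``basal_state`` set.
    """
    if G_b <= 0:
        raise ValueError("G_b must be positive")
    p0 = params.replace()
    p0.basal_glucose = G_b
    guess_x = _analytic_basal_guess(p0)
    Gp_b = G_b * params["VG"]
    others = [k for k in range(NSTATES) if k != IX["Gp"]]

    def resid(z):
        x = np.empty(NSTATES)
        x[IX["Gp"]] = Gp_b
        x[others] = z[:-1]
        pk = p0.replace(kp1=z[-1])
        return rhs(x, 0.0, 0.0, pk)

    z0 = np.concatenate([guess_x[others], [params["kp1"]]])
    sol = root(resid, z0, method="hybr", tol=1e-13)
    r = np.max(np.abs(resid(sol.x)))
    if r > 1e-9:
        raise CalibrationError(f"basal calibration failed (residual {r:.3g})")
    basal = np.empty(NSTATES)
    basal[IX["Gp"]] = Gp_b
    basal[others] = sol.x[:-1]
    out = params.replace(kp1=float(sol.x[-1]))
    out.basal_glucose = G_b
    out.basal_state = basal
    return out


def calibrate_insulin_sensitivity(params: PatientParameters,
                                  u_b: float = 0.0024,
                                  G_target: float | None = None,
                                  bracket=(0.005, 0.30)
                                  ) -> PatientParameters:
    """Calibrate Vmx so the steady state under u_I = u_b sits at G_target.

    With the supplied basal insulin rate the glucose level should settle
    at the clinical target (the Blood Glucose Index minimizer by
    default).  This pins the near-basal insulin sensitivity of the
    virtual patient.  The basal state is unaffected (Vmx acts only
    through remote insulin action, which vanishes at zero insulin).
    """
    from glyopt.metrics import bgi_minimizer

    if params.basal_state is None:
        raise CalibrationError("calibrate basal state first")
    if G_target is None:
        G_target = bgi_minimizer()

    def err(vmx):
        pk = params.replace(Vmx=vmx)
        pk.basal_glucose = params.basal_glucose
        pk.basal_state = params.basal_state.copy()
        ss = steady_state_under_constant_insulin(pk, u_b)
        return glucose_output(ss, pk) - G_target

    vmx = brentq(err, *bracket, xtol=1e-8, rtol=1e-10)
    out = params.replace(Vmx=float(vmx))
    out.basal_glucose = params.basal_glucose
    out.basal_state = params.basal_state.copy()
    return out


def basal_rate_for_target(params: PatientParameters, G_target: float,
                          bracket=(1e-4, 0.02)) -> float:
    """Constant insulin rate whose no-meal steady state equals G_target.

    Bisection on the steady-state glucose as a function of the rate
    (strictly decreasing: more insulin, lower glucose).
    """
    def err(u):
        ss = steady_state_under_constant_insulin(params, u)
        return glucose_output(ss, params) - G_target

    return float(brentq(err, *bracket, xtol=1e-7, rtol=1e-8))


def fasting_state_under_basal(params: PatientParameters, u_b: float
                              ) -> np.ndarray:
    """Initial condition for the therapy problems: fasting under u_I = u_b."""
    return steady_state_under_constant_insulin(params, u_b)


def default_patient() -> PatientParameters:
    """The bundled calibrated average adult patient."""
    from glyopt.params import load_average_adult

    return load_average_adult()
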