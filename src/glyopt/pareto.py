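"""Weight-tuning sweeps and Pareto-front analysis.

The scalarized objective weighs glucose risk against drug expenditure;
sweeping the weights traces the Pareto front between the integrated
risk Delta and the drug totals.  Two sweeps mirror the tuning
procedure: the mono-therapy sweep over epsilon = alpha_p / alpha_I
(insulin only) and the dual-therapy sweep over the glucagon weight
alpha_G at fixed (alpha_p, alpha_I).  A least-squares line fitted to
the (phi_I, phi_G) totals of the dual sweep yields the ad-hoc dosing
rule's coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace

import numpy as np

from glyopt.dosing import MealScenario
from glyopt.metrics import TherapyMetrics
from glyopt.ocp import GlucoseRegulationOCP, OCPConfig, OCPSolution
from glyopt.params import PatientParameters


@dataclass
class ParetoPoint:
    """One converged (or failed) solve of a weight sweep."""

    weight: float                  # the swept weight (epsilon or alpha_G)
    converged: bool
    metrics: TherapyMetrics | None
    objective: float | None
    p: int
    dual: bool

    def as_row(self) -> dict:
        row = {"weight": self.weight, "p": self.p, "dual": self.dual,
               "converged": self.converged}
        if self.metrics is not None:
            row.update(delta=self.metrics.delta, gmin=self.metrics.g_min,
                       gmax=self.metrics.g_max, phiI=self.metrics.phi_I,
                       phiG=self.metrics.phi_G)
        else:
            row.update(delta=np.nan, gmin=np.nan, gmax=np.nan,
                       phiI=np.nan, phiG=np.nan)
        return row


def log_grid(lo: float, hi: float, per_decade: int = 2) -> np.ndarray:
    """Logarithmic grid with ``per_decade`` points per decade, inclusive."""
    n = int(round(np.log10(hi / lo) * per_decade)) + 1
    return np.logspace(np.log10(lo), np.log10(hi), n)


def _sweep(patient: PatientParameters, meal: MealScenario,
           configs: list[OCPConfig], weights: np.ndarray
           ) -> list[ParetoPoint]:
    points = []
    warm: OCPSolution | None = None
    for w, cfg in zip(weights, configs):
        try:
            sol = GlucoseRegulationOCP(patient, meal, cfg).solve(
                warm_start=warm)
        except Exception:
            points.append(ParetoPoint(w, False, None, None, cfg.p,
                                      cfg.dual_hormone))
            continue
        if sol.success:
            warm = sol          # chain the warm start along the sweep
        points.append(ParetoPoint(w, bool(sol.success), sol.metrics,
                                  sol.objective, cfg.p, cfg.dual_hormone))
    return points


def sweep_epsilon(patient: PatientParameters, meal: MealScenario,
                  epsilons=None, p: int = 1,
                  base: OCPConfig | None = None) -> list[ParetoPoint]:
    """Mono-therapy sweep of epsilon = alpha_p / alpha_I (alpha_I = 1)."""
    if epsilons is None:
        epsilons = log_grid(1e-2, 1e5, 2)
    epsilons = np.asarray(epsilons, dtype=float)
    if np.any(epsilons <= 0) or np.any(np.diff(epsilons) <= 0):
        raise ValueError("epsilon grid must be positive and increasing")
    if base is None:
        base = OCPConfig()
    configs = [dc_replace(base, p=p, alpha_p=float(e), alpha_I=1.0,
                          dual_hormone=False) for e in epsilons]
    return _sweep(patient, meal, configs, epsilons)


def sweep_alpha_g(patient: PatientParameters, meal: MealScenario,
                  alpha_gs=None, p: int = 1,
                  base: OCPConfig | None = None) -> list[ParetoPoint]:
    """Dual-therapy sweep of the glucagon weight alpha_G.

    alpha_p and alpha_I stay at their selected values (10 and 1 for the
    minimum-fuel problem, 10^3 and 1 for minimum-energy).  The default
    grid extends to weights large enough that the optimum stops using
    glucagon, so the (phi_I, phi_G) front is traced end to end.
    """
    if alpha_gs is None:
        alpha_gs = log_grid(1e-4, 1e6, 1)
    alpha_gs = np.asarray(alpha_gs, dtype=float)
    if base is None:
        base = OCPConfig()
    alpha_p = 10.0 if p == 1 else 1e3
    configs = [dc_replace(base, p=p, alpha_p=alpha_p, alpha_I=1.0,
                          alpha_G=float(a), dual_hormone=True)
               for a in alpha_gs]
    return _sweep(patient, meal, configs, alpha_gs)


def fit_dose_relation(points: list[ParetoPoint],
                      require_glucagon: bool = True
                      ) -> tuple[float, float]:
    """Least-squares line phi_G = slope * phi_I + intercept (mg, mg/U).

    Only converged sweep points enter the fit; by default points whose
    optimum uses no glucagon are excluded (the rule applies only where
    glucagon is actually worth delivering).
    """
    phiI, phiG = [], []
    for pt in points:
        if not pt.converged or pt.metrics is None:
            continue
        if require_glucagon and pt.metrics.phi_G <= 1e-6:
            continue
        phiI.append(pt.metrics.phi_I)
        phiG.append(pt.metrics.phi_G)
    phiI = np.asarray(phiI)
    phiG = np.asarray(phiG)
    if phiI.size < 2 or np.ptp(phiI) < 1e-12:
        raise ValueError("need at least two points with distinct phi_I")
    slope, intercept = np.polyfit(phiI, phiG, 1)
    return float(slope), float(intercept)


def to_dataframe(points: list[ParetoPoint]):
    import pandas as pd

    return pd.DataFrame([pt.as_row() for pt in points])


def pareto_consistent(points: list[ParetoPoint], tol: float = 1e-6) -> bool:
    """No converged point strictly dominates another in (Delta, phi).

    phi is total insulin for mono sweeps and total glucagon for dual
    sweeps (the swept resource).
    """
    rows = [(pt.metrics.delta,
             pt.metrics.phi_G if pt.dual else pt.metrics.phi_I)
            for pt in points if pt.converged and pt.metrics is not None]
    for i, (d1, f1) in enumerate(rows):
        for j, (d2, f2) in enumerate(rows):
            if i != j and d1 < d2 - tol and f1 < f2 - tol:
                return False
    return True
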