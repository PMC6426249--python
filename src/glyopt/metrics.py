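"""The Blood Glucose Index risk functional and therapy-quality summaries.

The Blood Glucose Index (BGI) of Kovatchev and co-workers maps a glucose
concentration G (mg/dL) to a nonnegative clinical risk,

    BGI(G) = 10 * (1.509 * ((ln G)^1.084 - 5.3811))^2,

zero exactly at the clinically ideal level G_d = exp(5.3811^(1/1.084))
~ 112.51 mg/dL and growing toward both hypo- and hyperglycemia; the
asymmetric log transform makes equal risks correspond to the clinically
asymmetric 70/180 mg/dL target range.  A therapy over a horizon is
scored by the integrated risk Delta, the glucose extrema, and the total
drug amounts.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy.interpolate import PchipInterpolator

_A = 1.509
_B = 1.084
_C = 5.3811


def bgi(G):
    """Blood Glucose Index risk of a glucose level G (mg/dL), vectorized."""
    G = np.asarray(G, dtype=float)
    if np.any(G <= 0):
        raise ValueError("BGI is defined for positive glucose only")
    z = _A * (np.log(G) ** _B - _C)
    return 10.0 * z * z


def bgi_grad(G):
    """d BGI / dG."""
    G = np.asarray(G, dtype=float)
    lg = np.log(G)
    z = _A * (lg ** _B - _C)
    return 20.0 * z * _A * _B * lg ** (_B - 1.0) / G


def bgi_minimizer() -> float:
    """The glucose level G_d at which the risk vanishes (mg/dL)."""
    return float(np.exp(_C ** (1.0 / _B)))


@dataclass
class TherapyMetrics:
    """Summary measures scoring one therapy over a horizon."""

    delta: float          # integrated BGI (risk * min)
    g_min: float          # mg/dL
    g_max: float          # mg/dL
    phi_I: float          # total insulin (U)
    phi_G: float          # total glucagon (mg)
    t: np.ndarray = None          # grid for the cumulative dose curves
    r_I: np.ndarray = None        # cumulative insulin (U)
    r_G: np.ndarray = None        # cumulative glucagon (mg)

    def to_dict(self) -> dict:
        return {k: float(v) for k, v in asdict(self).items()
                if k in ("delta", "g_min", "g_max", "phi_I", "phi_G")}


def summarize(traj, refine: int = 4) -> TherapyMetrics:
    """Score a simulated trajectory.

    Delta is the composite-trapezoid integral of BGI(G(t)) on the
    trajectory grid; the glucose extrema are taken on a monotone-cubic
    resampling ``refine`` times denser than the grid, so an extremum
    falling between grid points is not missed; drug totals come from the
    schedule's own (analytic where possible) accumulation.
    """
    t = np.asarray(traj.t, dtype=float)
    if t.size < 2:
        raise ValueError("trajectory too short to summarize")
    G = np.asarray(traj.glucose, dtype=float)
    delta = float(np.trapezoid(bgi(G), t))
    # duplicated meal-boundary abscissae break strict monotonicity;
    # collapse them before interpolating
    keep = np.concatenate([[True], np.diff(t) > 0])
    if refine > 1 and np.count_nonzero(keep) > 3:
        dense_t = np.linspace(t[0], t[-1], refine * t.size)
        dense_G = PchipInterpolator(t[keep], G[keep])(dense_t)
    else:
        dense_G = G
    rI, rG = traj.schedule.cumulative(t)
    return TherapyMetrics(
        delta=delta,
        g_min=float(np.min(dense_G)),
        g_max=float(np.max(dense_G)),
        phi_I=float(rI[-1]),
        phi_G=float(rG[-1]),
        t=t, r_I=rI, r_G=rG,
    )
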