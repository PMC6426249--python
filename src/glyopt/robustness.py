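"""Robustness of fixed therapies: meal-variation maps and CVGA.

Two stress tests are applied to a therapy that was computed for the
nominal patient and the nominal meal:

* **meal grid** — the unchanged schedule is simulated under meals whose
  time and size differ from the planned ones; each cell reports the
  risk ratio Delta_bar/Delta and the glucose extrema, flagging severe
  hypoglycemia (G_min < 70 mg/dL) and the hyperglycemic regime
  (G_max > 300 mg/dL);
* **CVGA** (control variability grid analysis) — the schedule is applied
  to a cohort of parameter-perturbed patients and each outcome is
  classified by its (G_min, G_max) pair into risk zones.

The CVGA zone rectangles follow the standard published grid:
breakpoints 110/90/70/50 mg/dL on the minimum-glucose axis and
110/180/300/400 mg/dL on the maximum-glucose axis; "accurate" is the
inner zone (min >= 90, max <= 180) and "failure" the outer corner
(min < 70 and max > 300).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from glyopt.dosing import DosingSchedule, MealScenario
from glyopt.metrics import TherapyMetrics, summarize
from glyopt.model import fasting_state_under_basal, simulate
from glyopt.params import PatientParameters

#: zone-category breakpoints (mg/dL)
GMIN_BREAKS = (90.0, 70.0)        # >=90 | [70, 90) | <70
GMAX_BREAKS = (180.0, 300.0)      # <=180 | (180, 300] | >300

#: zone lookup by (min-category, max-category)
_ZONES = {
    (0, 0): "accurate",
    (0, 1): "benign", (1, 0): "benign", (1, 1): "benign",
    (0, 2): "hyper-risk", (1, 2): "hyper-risk",
    (2, 0): "hypo-risk", (2, 1): "hypo-risk",
    (2, 2): "failure",
}

SEVERE_HYPO = 70.0
HYPER_REGIME = 300.0


@dataclass(frozen=True)
class CVGAPoint:
    g_min: float
    g_max: float
    zone: str


def cvga_classify(g_min: float, g_max: float) -> str:
    """Map a (G_min, G_max) pair to its CVGA zone (total, deterministic)."""
    if g_min > g_max:
        raise ValueError("G_min exceeds G_max")
    lo = 0 if g_min >= GMIN_BREAKS[0] else (1 if g_min >= GMIN_BREAKS[1] else 2)
    hi = 0 if g_max <= GMAX_BREAKS[0] else (1 if g_max <= GMAX_BREAKS[1] else 2)
    return _ZONES[(lo, hi)]


@dataclass
class MealGridResult:
    """Long-format result of a meal-variation study."""

    tau: np.ndarray               # meal time per cell
    D: np.ndarray                 # meal grams per cell
    delta_ratio: np.ndarray       # Delta_bar / Delta_nominal
    g_max: np.ndarray
    g_min: np.ndarray
    failed: np.ndarray            # simulation failures

    @property
    def severe_hypo(self) -> np.ndarray:
        return self.g_min < SEVERE_HYPO

    @property
    def hyper_regime(self) -> np.ndarray:
        return self.g_max > HYPER_REGIME

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame({
            "tauD": self.tau, "D": self.D,
            "delta_ratio": self.delta_ratio,
            "gmax": self.g_max, "gmin": self.g_min,
            "severe_hypo": self.severe_hypo,
            "hyper_regime": self.hyper_regime,
            "failed": self.failed,
        })


def evaluate_meal_grid(schedule: DosingSchedule, patient: PatientParameters,
                       grid, nominal_metrics: TherapyMetrics,
                       basal_rate: float = 0.0024,
                       x0: np.ndarray | None = None) -> MealGridResult:
    """Simulate the unchanged schedule under every perturbed meal."""
    if x0 is None:
        x0 = fasting_state_under_basal(patient, basal_rate)
    cells = [meal for row in grid for meal in row]
    n = len(cells)
    tau = np.array([m.time for m in cells])
    D = np.array([m.grams for m in cells])
    dr = np.full(n, np.nan)
    gmx = np.full(n, np.nan)
    gmn = np.full(n, np.nan)
    failed = np.zeros(n, dtype=bool)
    for i, meal in enumerate(cells):
        try:
            traj = simulate(patient, x0, schedule, meal,
                            (schedule.t0, schedule.tf), rtol=1e-6, atol=1e-8)
            m = summarize(traj)
        except Exception:
            failed[i] = True
            continue
        dr[i] = m.delta / nominal_metrics.delta if nominal_metrics.delta > 0 \
            else np.inf
        gmx[i] = m.g_max
        gmn[i] = m.g_min
    return MealGridResult(tau, D, dr, gmx, gmn, failed)


@dataclass
class CVGAResult:
    points: list[CVGAPoint]
    zone_counts: dict
    accuracy_pct: float           # share of members in the accurate zone
    green_pct: float              # accurate + benign ("light + dark green")
    n_failed: int = 0

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame([{"gmin": p.g_min, "gmax": p.g_max,
                              "zone": p.zone} for p in self.points])


def cohort_cvga(schedule: DosingSchedule, cohort, meal: MealScenario,
                x0: np.ndarray | None = None, basal_rate: float = 0.0024,
                nominal: PatientParameters | None = None) -> CVGAResult:
    """Apply one fixed schedule to every cohort member and classify.

    The initial state is the *nominal* patient's fasting state (the
    therapy, including its starting condition, was designed for the
    nominal physiology).
    """
    if x0 is None:
        ref = nominal if nominal is not None else cohort[0]
        x0 = fasting_state_under_basal(ref, basal_rate)
    points = []
    failed = 0
    for member in cohort:
        try:
            traj = simulate(member, x0, schedule, meal,
                            (schedule.t0, schedule.tf), rtol=1e-6, atol=1e-8)
            m = summarize(traj)
        except Exception:
            failed += 1
            continue
        points.append(CVGAPoint(m.g_min, m.g_max,
                                cvga_classify(m.g_min, m.g_max)))
    counts: dict = {}
    for pt in points:
        counts[pt.zone] = counts.get(pt.zone, 0) + 1
    n_ok = len(points)
    acc = 100.0 * counts.get("accurate", 0) / n_ok if n_ok else np.nan
    green = 100.0 * (counts.get("accurate", 0) + counts.get("benign", 0)) \
        / n_ok if n_ok else np.nan
    return CVGAResult(points, counts, acc, green, failed)
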