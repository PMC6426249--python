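"""Explicit dosing rules: the standard insulin therapy and the ad-hoc dual therapy.

The *standard therapy* is the textbook open-loop regimen: a single
insulin bolus delivered half an hour before the meal on top of the
basal infusion.  The *ad-hoc dual therapy* augments it with glucagon:
a somewhat larger insulin bolus 30 min before the meal, followed by a
glucagon bolus 90 min after the meal whose size follows the linear
dose relation

    phi_G(phi_I) = 0.1596 * phi_I - 1.5796   (mg, clipped at zero),

the empirical relation between total insulin and total glucagon along
the dual-hormone Pareto front.  Boluses are realized as rectangular
pulses at the pump's maximum rate.
"""

from __future__ import annotations

import numpy as np

from glyopt.dosing import BolusEvent, DosingSchedule, MealScenario
from glyopt.metrics import TherapyMetrics, summarize
from glyopt.model import Trajectory, fasting_state_under_basal, simulate
from glyopt.params import PatientParameters

#: slope (mg/U) and intercept (mg) of the insulin->glucagon dose relation
DOSE_RELATION_SLOPE = 0.1596
DOSE_RELATION_INTERCEPT = -1.5796

#: default boost of the ad-hoc insulin bolus over the standard one; the
#: alternative 5% preset reflects a milder published recommendation
ADHOC_BOOST = 1.25
ADHOC_BOOST_CONSERVATIVE = 1.05


def glucagon_dose_rule(phi_I: float) -> float:
    """Glucagon total (mg) prescribed for an insulin total phi_I (U).

    Linear in phi_I with the Pareto-front coefficients; glucagon is used
    only where the relation is positive.
    """
    return max(0.0, DOSE_RELATION_SLOPE * phi_I + DOSE_RELATION_INTERCEPT)


def standard_therapy(meal: MealScenario, insulin_units: float = 10.0,
                     basal_rate: float = 0.0024, t0: float = 0.0,
                     tf: float = 300.0) -> DosingSchedule:
    """Basal infusion plus one insulin bolus 30 min before the meal."""
    onset = meal.time - 30.0
    if onset < t0:
        raise ValueError("bolus would start before the horizon")
    boluses = ()
    if insulin_units > 0:
        boluses = (BolusEvent("insulin", insulin_units, onset),)
    return DosingSchedule(t0, tf, basal_insulin=basal_rate, boluses=boluses)


def adhoc_dual_therapy(meal: MealScenario, standard_units: float = 10.0,
                       boost_factor: float = ADHOC_BOOST,
                       basal_rate: float = 0.0024, t0: float = 0.0,
                       tf: float = 300.0) -> DosingSchedule:
    """The ad-hoc dual-hormone schedule.

    Insulin: ``boost_factor * standard_units`` 30 min before the meal.
    Glucagon: the dose-rule amount 90 min after the meal; omitted when
    the rule gives zero.
    """
    phi_I = boost_factor * standard_units
    onset = meal.time - 30.0
    if onset < t0:
        raise ValueError("bolus would start before the horizon")
    boluses = [BolusEvent("insulin", phi_I, onset)]
    g = glucagon_dose_rule(phi_I)
    if g > 0:
        boluses.append(BolusEvent("glucagon", g, meal.time + 90.0))
    return DosingSchedule(t0, tf, basal_insulin=basal_rate,
                          boluses=tuple(boluses))


def evaluate_schedule(schedule: DosingSchedule, patient: PatientParameters,
                      meal: MealScenario | None,
                      x0: np.ndarray | None = None,
                      basal_rate: float = 0.0024,
                      ) -> tuple[Trajectory, TherapyMetrics]:
    """Simulate a fixed schedule from the fasting-under-basal state."""
    if x0 is None:
        x0 = fasting_state_under_basal(patient, basal_rate)
    traj = simulate(patient, x0, schedule, meal, (schedule.t0, schedule.tf))
    return traj, summarize(traj)


def compare_therapies(metrics_a: TherapyMetrics, metrics_b: TherapyMetrics
                      ) -> dict:
    """Which therapy wins on each measure (a vs b).

    Lower is better for delta, G_max and the drug totals; higher is
    better for G_min.
    """
    out = {}
    for field, better in [("delta", "lower"), ("g_max", "lower"),
                          ("g_min", "higher"), ("phi_I", "lower"),
                          ("phi_G", "lower")]:
        va, vb = getattr(metrics_a, field), getattr(metrics_b, field)
        if va == vb:
            out[field] = "tie"
        elif (va < vb) == (better == "lower"):
            out[field] = "a"
        else:
            out[field] = "b"
    return out
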