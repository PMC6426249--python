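"""Meal scenarios and drug infusion schedules.

A :class:`DosingSchedule` is the time-resolved pair of infusion rates
(insulin in U/min, glucagon in mg/min) over a horizon.  Two building
blocks are supported and may be combined:

* a constant basal insulin rate plus discrete :class:`BolusEvent` doses,
  each realized as a finite-width rectangular pulse at the pump's
  maximum rate (a Dirac bolus is unphysical: commercial pumps cap the
  instantaneous flow);
* sampled traces (e.g. optimal-control solutions at collocation nodes),
  interpolated piecewise-linearly and clipped to be nonnegative;
* piecewise-polynomial traces: the Lagrange interpolant of the node
  controls within each collocation element, i.e. exactly the control the
  pseudo-spectral transcription represents (clipped to the pump range).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import BarycentricInterpolator

#: maximum insulin flow of commercial pumps (U/min)
PUMP_MAX_INSULIN = 15.0
#: maximum glucagon flow of an insulin-like pump (mg/min)
PUMP_MAX_GLUCAGON = 0.15


@dataclass(frozen=True)
class MealScenario:
    """A meal modelled as an impulse of glucose into the solid stomach.

    Parameters
    ----------
    grams : glucose amount in grams (converted to mg internally).
    time : meal time tau_D in minutes.
    """

    grams: float
    time: float

    def __post_init__(self):
        if self.grams < 0:
            raise ValueError("meal glucose amount must be nonnegative")

    @property
    def milligrams(self) -> float:
        return 1000.0 * self.grams


@dataclass(frozen=True)
class BolusEvent:
    """A discrete drug dose delivered as a rectangular pulse.

    ``time`` is the pulse onset; the pulse width is ``amount / rate``
    with the rate defaulting to the pump maximum for the drug.
    """

    drug: str                      # "insulin" (U) or "glucagon" (mg)
    amount: float                  # U or mg
    time: float                    # onset, min
    rate: float | None = None      # delivery rate; None -> pump maximum

    def __post_init__(self):
        if self.drug not in ("insulin", "glucagon"):
            raise ValueError(f"unknown drug {self.drug!r}")
        if self.amount < 0:
            raise ValueError("bolus amount must be nonnegative")
        cap = PUMP_MAX_INSULIN if self.drug == "insulin" else PUMP_MAX_GLUCAGON
        rate = cap if self.rate is None else self.rate
        if not 0 < rate <= cap:
            raise ValueError(f"bolus rate {rate} outside (0, {cap}]")
        object.__setattr__(self, "rate", rate)

    @property
    def width(self) -> float:
        """Realized pulse width (min)."""
        return self.amount / self.rate


class DosingSchedule:
    """Insulin and glucagon infusion rates over ``[t0, tf]``."""

    def __init__(self, t0: float, tf: float, basal_insulin: float = 0.0,
                 boluses: tuple[BolusEvent, ...] = (),
                 trace_t: np.ndarray | None = None,
                 trace_uI: np.ndarray | None = None,
                 trace_uG: np.ndarray | None = None):
        if tf <= t0:
            raise ValueError("tf must exceed t0")
        if basal_insulin < 0:
            raise ValueError("basal insulin rate must be nonnegative")
        self.t0 = float(t0)
        self.tf = float(tf)
        self.basal_insulin = float(basal_insulin)
        self.boluses = tuple(boluses)
        for b in self.boluses:
            if b.time < t0 or b.time + b.width > tf:
                raise ValueError(
                    f"bolus at t={b.time} (width {b.width:.3g}) outside horizon")
        if trace_t is not None:
            self.trace_t = np.asarray(trace_t, dtype=float)
            if np.any(np.diff(self.trace_t) <= 0):
                raise ValueError("trace times must be strictly increasing")
            self.trace_uI = (np.zeros_like(self.trace_t) if trace_uI is None
                             else np.clip(np.asarray(trace_uI, float), 0.0, None))
            self.trace_uG = (np.zeros_like(self.trace_t) if trace_uG is None
                             else np.clip(np.asarray(trace_uG, float), 0.0, None))
        else:
            self.trace_t = None
            self.trace_uI = None
            self.trace_uG = None
        self._elements = []          # (t_nodes, uI_nodes, uG_nodes)
        self._interp_cache = None

    # -- constructors --------------------------------------------------

    @classmethod
    def constant(cls, t0: float, tf: float, uI: float, uG: float = 0.0
                 ) -> "DosingSchedule":
        t = np.array([t0, tf])
        return cls(t0, tf, trace_t=t, trace_uI=np.full(2, uI),
                   trace_uG=np.full(2, uG))

    @classmethod
    def from_samples(cls, t: np.ndarray, uI: np.ndarray,
                     uG: np.ndarray | None = None) -> "DosingSchedule":
        t = np.asarray(t, float)
        return cls(t[0], t[-1], trace_t=t, trace_uI=uI, trace_uG=uG)

    @classmethod
    def from_collocation(cls, elements) -> "DosingSchedule":
        """Piecewise-polynomial schedule from per-element node controls.

        ``elements`` is a sequence of ``(t_nodes, uI_nodes, uG_nodes)``
        covering contiguous time intervals; within each element the
        rates are the Lagrange interpolants of the node values, clipped
        to the pump range.
        """
        elements = [(np.asarray(t, float), np.asarray(uI, float),
                     None if uG is None else np.asarray(uG, float))
                    for t, uI, uG in elements]
        sched = cls(elements[0][0][0], elements[-1][0][-1])
        sched._elements = elements
        return sched

    # -- evaluation ----------------------------------------------------

    def _bolus_rate(self, t: np.ndarray, drug: str) -> np.ndarray:
        rate = np.zeros_like(t, dtype=float)
        for b in self.boluses:
            if b.drug != drug or b.amount == 0:
                continue
            rate += np.where((t >= b.time) & (t < b.time + b.width), b.rate, 0.0)
        return rate

    def _poly_rate(self, t: np.ndarray, which: int, cap: float) -> np.ndarray:
        if self._interp_cache is None:
            self._interp_cache = {}
            # fast path for element-wise constant traces
            consts = {0: [], 1: []}
            self._poly_const = None
            if all((np.ptp(uI) < 1e-14) and (uG is None or np.ptp(uG) < 1e-14)
                   for _, uI, uG in self._elements):
                edges = np.array([el[0][0] for el in self._elements]
                                 + [self._elements[-1][0][-1]])
                cI = np.array([el[1][0] for el in self._elements])
                cG = np.array([0.0 if el[2] is None else el[2][0]
                               for el in self._elements])
                self._poly_const = (edges, np.clip(cI, 0.0, None),
                                    np.clip(cG, 0.0, None))
        if self._poly_const is not None:
            edges, cI, cG = self._poly_const
            idx = np.clip(np.searchsorted(edges, t, side="right") - 1,
                          0, len(self._elements) - 1)
            return (cI if which == 0 else cG)[idx]
        out = np.zeros_like(t, dtype=float)
        for j, (tn, uI, uG) in enumerate(self._elements):
            un = uI if which == 0 else uG
            if un is None:
                continue
            lo = tn[0] if j > 0 else -np.inf
            hi = tn[-1] if j < len(self._elements) - 1 else np.inf
            mask = (t >= lo) & (t < hi) if j < len(self._elements) - 1 \
                else (t >= lo)
            if not np.any(mask):
                continue
            key = (j, which)
            if key not in self._interp_cache:
                self._interp_cache[key] = BarycentricInterpolator(tn, un)
            out[mask] = self._interp_cache[key](t[mask])
        return np.clip(out, 0.0, cap)

    def insulin_rate(self, t) -> np.ndarray:
        """u_I(t) in U/min (vectorized)."""
        scalar = np.ndim(t) == 0
        t = np.atleast_1d(np.asarray(t, dtype=float))
        out = np.full(t.shape, self.basal_insulin)
        out += self._bolus_rate(t, "insulin")
        if self.trace_t is not None:
            out += np.interp(t, self.trace_t, self.trace_uI)
        if self._elements:
            out += self._poly_rate(t, 0, PUMP_MAX_INSULIN)
        return out[0] if scalar else out

    def glucagon_rate(self, t) -> np.ndarray:
        """u_G(t) in mg/min (vectorized)."""
        scalar = np.ndim(t) == 0
        t = np.atleast_1d(np.asarray(t, dtype=float))
        out = self._bolus_rate(t, "glucagon")
        if self.trace_t is not None:
            out += np.interp(t, self.trace_t, self.trace_uG)
        if self._elements:
            out += self._poly_rate(t, 1, PUMP_MAX_GLUCAGON)
        return out[0] if scalar else out

    # -- bookkeeping ---------------------------------------------------

    def breakpoints(self) -> np.ndarray:
        """Times where a rate is discontinuous (integration restarts)."""
        pts = {self.t0, self.tf}
        for b in self.boluses:
            if b.amount > 0:
                pts.add(b.time)
                pts.add(b.time + b.width)
        for tn, _, _ in self._elements:
            pts.add(float(tn[0]))
            pts.add(float(tn[-1]))
        return np.array(sorted(p for p in pts if self.t0 <= p <= self.tf))

    def cumulative(self, t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Cumulative doses r_I(t) (U) and r_G(t) (mg) on a grid ``t``.

        Boluses and basal are accumulated analytically; sampled traces by
        trapezoidal quadrature on the union of ``t`` and the trace knots.
        """
        t = np.asarray(t, dtype=float)
        rI = self.basal_insulin * (t - self.t0)
        rG = np.zeros_like(t)
        for b in self.boluses:
            delivered = np.clip(t - b.time, 0.0, b.width) * b.rate
            if b.drug == "insulin":
                rI = rI + delivered
            else:
                rG = rG + delivered
        if self.trace_t is not None:
            grid = np.union1d(t, self.trace_t)
            uI = np.interp(grid, self.trace_t, self.trace_uI)
            uG = np.interp(grid, self.trace_t, self.trace_uG)
            cI = np.concatenate([[0.0], np.cumsum(np.diff(grid) * 0.5 * (uI[1:] + uI[:-1]))])
            cG = np.concatenate([[0.0], np.cumsum(np.diff(grid) * 0.5 * (uG[1:] + uG[:-1]))])
            rI = rI + np.interp(t, grid, cI)
            rG = rG + np.interp(t, grid, cG)
        if self._elements:
            # integrate element by element so the trapezoid never spans a
            # control discontinuity at an element boundary; a fine grid
            # resolves clipped polynomial lobes inside the element
            all_t, all_cI, all_cG = [], [], []
            baseI = baseG = 0.0
            for tn, uI_n, uG_n in self._elements:
                m = max(int(np.ceil((tn[-1] - tn[0]) / 0.1)), 2)
                tg = np.linspace(tn[0], tn[-1], m + 1)
                ui = np.clip(BarycentricInterpolator(tn, uI_n)(tg),
                             0.0, PUMP_MAX_INSULIN)
                ug = (np.zeros_like(tg) if uG_n is None else
                      np.clip(BarycentricInterpolator(tn, uG_n)(tg),
                              0.0, PUMP_MAX_GLUCAGON))
                cI = baseI + np.concatenate(
                    [[0.0], np.cumsum(np.diff(tg) * 0.5 * (ui[1:] + ui[:-1]))])
                cG = baseG + np.concatenate(
                    [[0.0], np.cumsum(np.diff(tg) * 0.5 * (ug[1:] + ug[:-1]))])
                baseI, baseG = cI[-1], cG[-1]
                all_t.append(tg)
                all_cI.append(cI)
                all_cG.append(cG)
            grid = np.concatenate(all_t)
            rI = rI + np.interp(t, grid, np.concatenate(all_cI))
            rG = rG + np.interp(t, grid, np.concatenate(all_cG))
        return rI, rG

    def total_insulin(self) -> float:
        """phi_I: total insulin delivered over the horizon (U)."""
        return float(self.cumulative(np.array([self.tf]))[0][0])

    def total_glucagon(self) -> float:
        """phi_G: total glucagon delivered over the horizon (mg)."""
        return float(self.cumulative(np.array([self.tf]))[1][0])
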