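"""Patient parameters for the glucose-insulin-glucagon model.

A *virtual patient* is the full vector of physiological constants of the
17-state model (rate constants, volumes, sensitivities, body weight),
together with derived basal quantities: the basal glucose level ``G_b``
and the basal steady state reached with zero exogenous input and no meal.

Parameters are stored keyed by their conventional symbol names (``VG``,
``k1``, ``kp2``, ``Vmx``, ...).  A bundled file ``data/average_adult.json``
holds the average adult patient used throughout; its free parameters are
calibrated so that the basal glucose is 130 mg/dL and a constant basal
insulin infusion of 0.0024 U/min steers glucose to the clinical target
112.51 mg/dL.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

#: Names of the 17 state variables, in model order.
STATE_NAMES = (
    "Gp",     # x1  mass of glucose in plasma (mg/kg)
    "Gt",     # x2  mass of glucose in tissue (mg/kg)
    "Il",     # x3  mass of insulin in liver (pmol/kg)
    "Ip",     # x4  mass of insulin in plasma (pmol/kg)
    "I1",     # x5  delayed insulin signal, first compartment (pmol/L)
    "XL",     # x6  delayed insulin action on EGP (pmol/L)
    "Qsto1",  # x7  solid glucose in stomach (mg)
    "Qsto2",  # x8  liquid glucose in stomach (mg)
    "Qgut",   # x9  glucose in intestine (mg)
    "X",      # x10 insulin action in interstitial fluid (pmol/L)
    "SRHs",   # x11 static glucagon secretion (ng/L/min)
    "H",      # x12 plasma glucagon (ng/L)
    "XH",     # x13 delayed glucagon action on EGP (ng/L)
    "Isc1",   # x14 nonmonomeric insulin in subcutaneous space (pmol/kg)
    "Isc2",   # x15 monomeric subcutaneous insulin (pmol/kg)
    "Hsc1",   # x16 subcutaneous glucagon, first compartment (ng/L)
    "Hsc2",   # x17 subcutaneous glucagon, second compartment (ng/L)
)

NSTATES = len(STATE_NAMES)

#: index of each state in the state vector
IX = {name: i for i, name in enumerate(STATE_NAMES)}

#: Parameter symbols the right-hand side requires (everything else in a
#: parameter file is carried along but unused by the dynamics).
REQUIRED_SYMBOLS = (
    # glucose kinetics
    "VG", "k1", "k2",
    # endogenous glucose production
    "kp1", "kp2", "kp3", "ki", "xi",
    # glucose utilization
    "Fcns", "Vm0", "Vmx", "Km0", "p2U", "Ib",
    # renal excretion
    "ke1", "ke2",
    # meal absorption
    "kmax", "kmin", "kabs", "kgri", "f", "b", "c",
    # insulin kinetics
    "VI", "m1", "m2", "m3", "m4",
    # subcutaneous insulin
    "kd", "ka1", "ka2",
    # glucagon kinetics and secretion
    "n", "Hb", "SRHb", "rho", "sigma", "delta", "Gth", "kH", "VH",
    # subcutaneous glucagon
    "kh1", "kh2", "kh3",
    # anthropometrics and input conversions
    "BW", "U_to_pmol", "mg_to_ng",
    # smoothing widths of the four non-differentiable terms
    "w_egp", "w_renal", "w_srhs", "w_srhd", "w_xh",
)

#: Physiological parameters subject to inter/intra-patient variability.
#: Unit-conversion constants, smoothing widths and anthropometrics are
#: excluded: they are either numerical devices or directly measured.
PERTURBABLE_SYMBOLS = (
    "VG", "k1", "k2", "kp1", "kp2", "kp3", "ki", "xi",
    "Vm0", "Vmx", "Km0", "p2U",
    "ke1", "ke2", "kmax", "kmin", "kabs", "kgri", "f",
    "VI", "m1", "m2", "m3", "m4", "kd", "ka1", "ka2",
    "n", "Hb", "SRHb", "rho", "sigma", "delta", "kH", "VH",
    "kh1", "kh2", "kh3",
)


class MissingParameterError(KeyError):
    """A symbol required by the model right-hand side is absent."""


@dataclass
class PatientParameters:
    """Complete physiological parameter vector plus basal quantities.

    Parameters
    ----------
    values
        Mapping from symbol name to value.  Must cover
        :data:`REQUIRED_SYMBOLS`.
    basal_glucose
        Basal (fasting, zero-input) glucose level G_b in mg/dL, or None
        before calibration.
    basal_state
        The 17-component steady state under zero exogenous input and no
        meal, or None before calibration.
    """

    values: dict = field(default_factory=dict)
    basal_glucose: float | None = None
    basal_state: np.ndarray | None = None

    def __post_init__(self):
        missing = [s for s in REQUIRED_SYMBOLS if s not in self.values]
        if missing:
            raise MissingParameterError(
                f"missing model parameter symbol(s): {', '.join(missing)}")
        if self.basal_state is not None:
            self.basal_state = np.asarray(self.basal_state, dtype=float)
            if self.basal_state.shape != (NSTATES,):
                raise ValueError("basal_state must have 17 components")
        for sym in ("VG", "BW"):
            if self.values[sym] <= 0:
                raise ValueError(f"{sym} must be positive")

    def __getitem__(self, symbol: str) -> float:
        try:
            return self.values[symbol]
        except KeyError:
            raise MissingParameterError(
                f"unknown model parameter symbol {symbol!r}") from None

    def replace(self, **updates) -> "PatientParameters":
        """Copy with some symbol values replaced (basal data carried over)."""
        vals = dict(self.values)
        vals.update(updates)
        return PatientParameters(vals, self.basal_glucose,
                                 None if self.basal_state is None
                                 else self.basal_state.copy())

    def scaled(self, factors: dict) -> "PatientParameters":
        """Copy with symbols multiplied by per-symbol factors.

        The basal state is *not* recalibrated: a perturbed patient keeps
        the nominal basal bookkeeping, mirroring the application of a
        nominal-patient therapy to a perturbed physiology.
        """
        vals = dict(self.values)
        for sym, fac in factors.items():
            vals[sym] = vals[sym] * fac
        return PatientParameters(vals, self.basal_glucose,
                                 None if self.basal_state is None
                                 else self.basal_state.copy())

    # -- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        out = {"values": dict(self.values)}
        if self.basal_glucose is not None:
            out["basal_glucose"] = self.basal_glucose
        if self.basal_state is not None:
            out["basal_state"] = dict(zip(STATE_NAMES, self.basal_state.tolist()))
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "PatientParameters":
        basal = d.get("basal_state")
        if basal is not None:
            basal = np.array([basal[name] for name in STATE_NAMES], dtype=float)
        return cls(dict(d["values"]), d.get("basal_glucose"), basal)

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)

    @classmethod
    def from_file(cls, path) -> "PatientParameters":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def load_average_adult() -> PatientParameters:
    """The bundled average adult virtual patient (calibrated to G_b = 130)."""
    text = resources.files("glyopt.data").joinpath("average_adult.json").read_text()
    return PatientParameters.from_dict(json.loads(text))
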