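"""Shared fixtures: the calibrated patient, the nominal meal, and the
four optimal-therapy solutions (session-scoped; the solves are the
expensive part of the suite and every consumer shares them)."""

from __future__ import annotations

import numpy as np
import pytest

from glyopt import model as gm
from glyopt.dosing import MealScenario
from glyopt.ocp import GlucoseRegulationOCP, OCPConfig


@pytest.fixture(scope="session")
def patient():
    return gm.default_patient()


@pytest.fixture(scope="session")
def meal():
    return MealScenario(70.0, 60.0)


@pytest.fixture(scope="session")
def x_fasting(patient):
    """Fasting state under the basal rate: the therapy initial condition."""
    return gm.fasting_state_under_basal(patient, 0.0024)


@pytest.fixture(scope="session")
def mono_remf(patient, meal):
    return GlucoseRegulationOCP(patient, meal, OCPConfig(p=1)).solve()


@pytest.fixture(scope="session")
def dual_remf(patient, meal, mono_remf):
    cfg = OCPConfig(p=1, dual_hormone=True)
    return GlucoseRegulationOCP(patient, meal, cfg).solve(
        warm_start=mono_remf)


@pytest.fixture(scope="session")
def mono_reme(patient, meal):
    return GlucoseRegulationOCP(patient, meal, OCPConfig(p=2, alpha_p=1e3)).solve()


@pytest.fixture(scope="session")
def dual_reme(patient, meal, mono_reme):
    cfg = OCPConfig(p=2, alpha_p=1e3, dual_hormone=True)
    return GlucoseRegulationOCP(patient, meal, cfg).solve(
        warm_start=mono_reme)
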