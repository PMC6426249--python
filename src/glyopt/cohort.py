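"""Virtual patient cohorts and meal-scenario grids for robustness studies.

A cohort member is the nominal patient with every physiological
parameter independently multiplied by ``1 + phi``, where phi is a
zero-mean Gaussian perturbation truncated at a relative bound (default
sigma = 0.067 with |phi| <= 0.2, i.e. parameters within 20% of
nominal, the truncation sitting at three sigma).  The basal state is
deliberately *not* recalibrated: the study applies therapies computed
for the nominal patient to physiologies that differ from it, so the
perturbed dynamics start from the nominal initial condition.

Meal uncertainty is modelled as a rectangular grid over meal time and
glucose amount.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from glyopt.dosing import MealScenario
from glyopt.params import PERTURBABLE_SYMBOLS, PatientParameters

#: default perturbation spread: "up to 20%" with the bound at 3 sigma
DEFAULT_SIGMA = 0.067
DEFAULT_TRUNCATION = 0.20


@dataclass(frozen=True)
class CohortSpec:
    """Recipe for a reproducible perturbed-patient cohort."""

    n: int
    sigma: float = DEFAULT_SIGMA
    truncation: float | None = DEFAULT_TRUNCATION
    seed: int = 0
    shared_draw: bool = False     # one phi for all parameters of a member

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("cohort size must be at least 1")
        if self.sigma < 0:
            raise ValueError("sigma must be nonnegative")
        if self.truncation is not None and self.truncation >= 1.0 and \
                self.sigma > 0.5:
            raise ValueError("perturbation could drive parameters negative")


def _draw_phi(rng: np.random.Generator, size: int, sigma: float,
              truncation: float | None) -> np.ndarray:
    """Truncated-normal factors by rejection (exact distribution)."""
    if sigma == 0.0:
        return np.zeros(size)
    phi = rng.normal(0.0, sigma, size)
    if truncation is not None:
        bad = np.abs(phi) > truncation
        while np.any(bad):
            phi[bad] = rng.normal(0.0, sigma, int(bad.sum()))
            bad = np.abs(phi) > truncation
    return phi


def perturb_parameters(base: PatientParameters, spec: CohortSpec
                       ) -> list[PatientParameters]:
    """Generate the cohort; a pure function of (base, spec)."""
    rng = np.random.default_rng(spec.seed)
    cohort = []
    syms = PERTURBABLE_SYMBOLS
    for _ in range(spec.n):
        if spec.shared_draw:
            phi = np.full(len(syms), _draw_phi(rng, 1, spec.sigma,
                                               spec.truncation)[0])
        else:
            phi = _draw_phi(rng, len(syms), spec.sigma, spec.truncation)
        factors = {s: 1.0 + f for s, f in zip(syms, phi)}
        member = base.scaled(factors)
        if any(member[s] <= 0 for s in syms):
            raise ValueError("perturbation produced a nonpositive parameter")
        cohort.append(member)
    return cohort


def meal_scenarios(tau_range=(30.0, 90.0), D_range=(40.0, 100.0),
                   steps: int = 7) -> list[list[MealScenario]]:
    """Rectangular meal grid: ``steps`` x ``steps`` scenarios.

    Returned row-major as a nested list ``grid[i][j]`` with meal time
    varying along i and meal size (grams) along j; both endpoints are
    included, and for odd step counts over the default ranges the
    nominal (60 min, 70 g) scenario lies on the grid.
    """
    if steps < 2:
        raise ValueError("need at least 2 steps per axis")
    t0, t1 = tau_range
    d0, d1 = D_range
    if not (t1 > t0 and d1 > d0):
        raise ValueError("degenerate scenario range")
    taus = np.linspace(t0, t1, steps)
    doses = np.linspace(d0, d1, steps)
    return [[MealScenario(float(D), float(tau)) for D in doses]
            for tau in taus]


def export_cohort(cohort: list[PatientParameters], spec: CohortSpec,
                  directory) -> None:
    """One parameter file per member plus a manifest of the recipe."""
    import json
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for i, member in enumerate(cohort):
        member.to_file(directory / f"member_{i:04d}.json")
    manifest = {"n": spec.n, "sigma": spec.sigma,
                "truncation": spec.truncation, "seed": spec.seed,
                "shared_draw": spec.shared_draw}
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
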