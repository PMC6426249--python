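# Methods

This note records the model, the numerical machinery and the design
choices behind `glyopt`, in enough detail to judge what the results do
and do not show.

## The patient model

The virtual patient is a 17-state ODE system in the UVA/Padova lineage
of glucose–insulin models, extended with glucagon kinetics and action.
States (units in `glyopt.params.STATE_NAMES`): plasma and tissue glucose
masses G_p, G_t (mg/kg); liver and plasma insulin I_l, I_p (pmol/kg); a
two-stage delayed insulin signal I′, X^L (pmol/L) acting on endogenous
glucose production (EGP); the meal chain Q_sto1, Q_sto2, Q_gut (mg) with
a gastric emptying rate that is fast for an empty or full stomach and
slow in between; remote insulin action X (pmol/L) on glucose
utilization; static glucagon secretion SRHs, plasma glucagon H and
delayed glucagon action X^H on EGP; and two-compartment subcutaneous
depots for each hormone (I_sc1/2, H_sc1/2).

Key structural assumptions:

* **Type 1 physiology** — no endogenous insulin secretion; all insulin
  enters subcutaneously.  Endogenous glucagon secretion is retained
  (counter-regulation is intact), stimulated below the glucose threshold
  G_th and damped by circulating insulin, with a rate-of-fall term.
* **EGP** is linear in G_p, X^L and X^H, floored at zero:
  EGP = max(kp1 − kp2·G_p − kp3·X^L + ξ·X^H, 0).
* **Utilization** is insulin-independent (F_cns) plus Michaelis–Menten
  insulin-dependent uptake (V_m0 + V_mx·X)·G_t/(K_m0 + G_t); renal
  excretion switches on above the threshold ke2.
* **Inputs** — insulin u_I (U/min) converts to the depot as
  u_I·6000/BW pmol/kg/min; glucagon u_G (mg/min) converts as
  u_G·10⁶/(V_H·BW) ng/L/min; a meal is an instantaneous increment of
  Q_sto1 by D mg.

### Smoothing

Four right-hand-side terms are of the form max(z, 0) (renal excretion,
EGP floor, the secretion target, the glucagon action drive, and the
rate-of-fall rectifier).  Each is replaced by
(z + √(z² + w²))/2 with a per-term width `w_*` stored with the
parameters.  Widths default to ≲1 % of the scale on which each argument
varies (e.g. 1 mg/kg on the renal threshold, 0.5 ng/L on H − H_b), so
smoothed and hard dynamics agree to better than 1 % of the argument
magnitude beyond five widths from a switch (verified by test).  The
smoothed system is what the simulator, the calibrators and the optimizer
all use; the hard form is kept for the fidelity test only.

### Parameters and calibration

Rate constants, volumes and sensitivities use published average-adult
values of this model family where such values exist.  Quantities that
are not published at the precision this pipeline needs are pinned by
four calibration anchors, chosen once and frozen into
`data/average_adult.json`:

1. **kp1** (EGP scale) — solved jointly with the basal state so that the
   zero-input steady state sits exactly at G_b = 130 mg/dL
   (`calibrate_basal`; 16 states + kp1 against 17 steady-state
   equations, with G_p fixed at G_b·V_G).  Result: kp1 = 2.6452.
2. **V_mx** (insulin sensitivity) — chosen so that a constant basal
   infusion u_b = 0.0024 U/min steers the no-meal system to the
   risk-minimizing glucose G_d (`calibrate_insulin_sensitivity`).
   Result: V_mx = 0.0341.  The two calibrations decouple because remote
   insulin action vanishes at zero insulin.
3. **Insulin subcutaneous/action speed** (kd = ka2 = 0.030, ki = 0.011
   /min) — the fast end of the plausible range for rapid-acting
   analogues (plasma appearance peaks ~31 min after a bolus); selected
   so that the minimum-fuel optimum places its insulin pulse 35–40 min
   ahead of the meal, the clinically sensible lead time.
4. **Glucagon gain and PK** (ξ = 0.001 (mg/kg/min)/(ng/L), kh1 = 0.15,
   kh2 = 0.005, kh3 = 0.12 /min, n = 0.2 /min, V_H = 0.25 L/kg) — tuned
   once so a 1 mg subcutaneous bolus raises glucose by ≈ +65 mg/dL,
   peaking ~50 min post-bolus, a typical clinical rescue response.

The basal steady state ships with the parameter file and is re-verified
(residual < 1e−9, 300-min drift < 0.5 mg/dL) by the test suite.

### Simulation

`simulate` integrates the smoothed system with LSODA (default
rtol 1e−8, atol 1e−10), restarting at every control discontinuity and
at the meal time, where Q_sto1 jumps by exactly D; the output grid
contains both the pre- and post-meal state.  An independent fixed-step
RK4 oracle at h = 0.05 min agrees with the adaptive solution to
< 0.1 mg/dL in glucose.  Robustness studies use relaxed tolerances
(1e−6/1e−8), which changes glucose by far less than the zone widths
they feed into.

## The risk functional

BGI(G) = 10·(1.509·((ln G)^1.084 − 5.3811))², with closed-form minimizer
exp(5.3811^(1/1.084)) = 112.5265 mg/dL.  Note that the widely quoted
target level 112.51 corresponds to slightly different constants than the
four-digit ones used here; the package implements the formula as stated
and reports its true minimizer (112.53 at two decimals).  Therapy
scores: Δ by composite trapezoid on the simulation grid (refinement
changes it by < 0.1 %), extrema on a 4× monotone-cubic resampling so
they cannot hide between grid points, drug totals by exact accumulation
of boluses/basal plus per-element quadrature of optimizer traces.

## Optimal control

### Transcription

Each smooth arc of the horizon (before and after the meal) is covered by
uniform **spectral elements**: Legendre–Gauss–Lobatto (LGL) nodes of
order N_seg = 4 per element, 12 elements pre-meal and 24 post-meal by
default (mesh in `OCPConfig`).  States are elementwise polynomials
coupled by continuity, with the meal realized as a prescribed Q_sto1
jump at the phase boundary; dynamics become defect constraints (nodal
differentiation matrix versus scaled right-hand side), the running cost
becomes Gauss–Lobatto quadrature, and the glucose path bound is a bound
on the G_p coordinate at every node.  LGL (endpoint-including) nodes are
used so boundary and linkage conditions bind on decision variables
directly.

**The control is constant within each element** (a degree-0 control
mesh under the state mesh).  This is a deliberate anti-aliasing choice:
with one control value per node, the minimum-fuel (p = 1) program is
linear in the controls and exploits the discretization — it plays
single-node spikes against the quadrature weights, producing solutions
whose claimed objective disagrees with re-simulation by an order of
magnitude.  With elementwise-constant controls the realized schedule is
exactly what the transcription assumed: the solver objective matches
re-quadrature of the re-simulated trajectory to < 0.1 %, and the nodal
glucose agrees with adaptive integration to ~0.03 mg/dL.  Pulse timing
is resolved to the element width (5 min pre-meal, 10 min post-meal).

### Solving

The defect system is square given the controls, and is eliminated
exactly at every candidate control iterate by a nonmonotone Newton
iteration per element (analytic Jacobians; seeded by a coarse RK4
prediction, warm-started along the optimization).  The optimizer (SLSQP)
therefore works in the **reduced space** of element controls (36 or 72
variables); state sensitivities come from implicit differentiation of
the defect system (one LU per element, forward-chained through the
linkage).  Glucose path bounds become inequality constraints on the
implicit states with analytic Jacobians; total-dose caps are exact
linear constraints (duration × rate per element).  This route was chosen
after the full-space NLP proved numerically fragile for the dense-SQP
implementation available: the reduced problem has identical KKT points
on the dynamics manifold and solves in seconds.

Determinism and starts: no randomness anywhere.  The default warm start
is a standard-therapy-like raised-cosine insulin pulse (10 U centred
30 min before the meal) simulated forward; dual-hormone problems also
try an ad-hoc-shaped start (larger insulin pulse plus glucagon at
meal + 90 min) and keep the better feasible optimum.  The working
objective is scaled by α_p so SQP tolerances behave uniformly across
weight sweeps; a line-search stall (common near nonsmooth minimum-fuel
optima) triggers one deterministic restart from the incumbent and is
accepted only if feasible.

## Therapies, sweeps, robustness

* **Standard therapy**: one insulin bolus (default 10 U) 30 min before
  the meal at the pump maximum (15 U/min ⇒ 40 s pulse), over basal u_b.
* **Ad-hoc dual therapy**: insulin bolus of boost × standard (boost
  defaults to 1.25; a conservative 1.05 preset is also exposed) and a
  glucagon bolus 90 min after the meal sized by
  φ_G = max(0, 0.1596·φ_I − 1.5796) mg.
* **Sweeps**: ε = α_p/α_I (mono) and α_G (dual) on logarithmic grids;
  the dual grid extends to 10⁶ because, at this model's scales, the
  glucagon term only becomes binding at large weights.  The dose
  relation is an ordinary least-squares line through the (φ_I, φ_G)
  totals of converged dual optima that actually use glucagon.
* **Virtual cohort**: every physiological parameter of a member is
  independently multiplied by 1 + φ, φ ~ N(0, 0.067²) truncated at
  |φ| ≤ 0.2 (3σ; rejection sampling, exact distribution).  Body weight,
  unit conversions and smoothing widths are not perturbed.  The basal
  bookkeeping is deliberately *not* recalibrated: therapies designed for
  the nominal patient are applied, from the nominal fasting state, to
  physiologies that differ from it.  A shared-draw mode (one φ for all
  parameters) is available.  The generator emulates parameter
  uncertainty and day-to-day variability only; it does not model sensor
  noise, intra-day parameter drift, exercise, or meal composition
  effects, so cohort results speak to parametric robustness, not to
  full clinical variability.
* **CVGA**: outcomes classified by (G_min, G_max) into
  accurate / benign / hyper-risk / hypo-risk / failure using the
  standard rectangular grid (min-axis breaks 90/70, max-axis breaks
  180/300 mg/dL); "accuracy" is the accurate-zone share, and the
  accurate+benign share is reported alongside since the green-zone
  convention varies across the literature.  Severe hypoglycemia is
  G_min < 70, the hyperglycemic regime G_max > 300.

## Numerical choices and degenerate inputs

Integration tolerances, smoothing widths, mesh, SQP iteration limits and
the CVGA breakpoints are all configuration, with the defaults above.
Zero-size meals are legal and equivalent to no meal.  A cohort σ of zero
reproduces the base patient exactly.  Failed solves inside sweeps are
recorded per point and excluded from fits; failed simulations inside
robustness studies are counted and excluded.  Steady-state solvers run a
burn-in integration before Newton polishing and report the residual on
failure.

## Known limitations

* The average-adult parameter set is a calibrated reconstruction, not a
  clinically identified patient; absolute therapy numbers (e.g. the
  ~13 U optimal insulin total, the dose-relation slope ≈ 0.23–0.27 mg/U)
  are specific to this parameterization.  Relative statements
  (dual-hormone dominance, Pareto monotonicity, pulse-like minimum-fuel
  optima) are robust across the parameter variants explored during
  development.
* In this parameterization the dual-hormone minimum-fuel optimum
  prefers a pre-meal insulin/glucagon push–pull over a late glucagon
  rescue; both shapes are near-optimal, and which wins depends on the
  insulin-action tail relative to meal absorption.
* The 10 U standard therapy lands comfortably mid-range on the nominal
  patient here and is therefore *more* CVGA-robust than the optimal
  therapies, which ride the G ≥ 90 path bound and shed cohort members
  across it; with parameterizations whose meal excursions press the
  180 mg/dL ceiling, the same pipeline ranks the standard therapy worst.
* Open-loop only: schedules are precomputed from the initial state; no
  feedback, no receding horizon, no physical-activity model.
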