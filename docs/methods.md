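# Methods

## Model and assumptions

The simulator integrates a four-state competition model of tumor growth under
chemo-immunotherapy: normal cells (x1) and cancer cells (x2) grow
logistically and compete; immune cells (x3) are recruited at a constant
influx α plus a Michaelis–Menten response p·x3·x2/(s + x2), and are consumed
by cancer encounters; a one-compartment drug balance C' = vc(t) − f2·C couples
into all three cell equations through first-order kill terms. All populations
are normalized so that 1 is the carrying-capacity scale, and time is measured
in days, with a default 100-day horizon (the window over which treatment
effects on the body are assessed).

Two modeling conventions deserve emphasis:

* **Population-independent drug kill.** The kill terms enter as `−r·C`, not
  mass-action `−r·C·x`. This is the model form implemented throughout. Its
  consequence is that the zero-population states are not invariant under
  dosing, which is why the integrator clamps states at zero (below).
* **The control is a correction term, not an infusion.** The input μ acts
  additively on the cancer equation and may take either sign; its
  nonnegativity is deliberately not enforced.

## Default parameter values

The rate constants are configurable everywhere and never hard-coded inside
operations. The shipped defaults are the standard normalized constants of the
De Pillis–Radunskaya competition model, mapped onto this model's symbols:

| symbol | value | meaning |
|--------|-------|---------|
| a1, a2 | 1.5, 1.0 | cancer / normal growth rates (1/day) |
| d1, d2 | 1.0, 1.0 | inverse carrying capacities |
| e1, e2, e3, e4 | 1.0, 0.5, 1.0, 1.0 | competition/kill cross terms |
| r1, r2, r3 | 0.2, 0.3, 0.1 | drug kill coefficients (immune, cancer, normal) |
| f1, f2 | 0.2, 1.0 | immune death rate, drug washout rate |
| α, p, s | 0.33, 0.01, 0.3 | immune influx, response rate, half-saturation |

Under this frozen set the treated steady state of the normal-cell equation
with a constant dose near 1 is x1 ≈ 0.887, which satisfies the x1 ≥ 0.75
safety floor the scenarios are required to maintain; the set was chosen once
and is not adjusted per scenario.

Controller defaults follow the customary working values: SMC with ∂ = 1,
m1 = 1, η = 0 (gain ρ estimated online each step); SC with m2 = 1,
τ_a = 0.01 day. τ_a is the single most consequential tuning knob: the closed
loop is exactly x2' = −x2/τ_a, so the elimination time under threshold ε is
τ_a·ln(x2(0)/ε) — about 0.055 days at τ_a = 0.01 and ε = 10⁻³, comfortably
inside the five-day bound reported for this scenario.

## Dose schedules and calibration

Two infusion modes are modeled: constant vc(t) = v and exponentially decaying
("continuous") vc(t) = v·e^(−λt). Pulsed protocols are out of scope. The
drug concentration from C(0) = 0 has the closed forms
(v/f2)(1 − e^(−f2·t)) and v(e^(−λt) − e^(−f2·t))/(f2 − λ) respectively, used
both by the collocation objectives and as integrator oracles.

The shipped amplitudes are calibrated so that the 100-day mean concentration
matches the reported working averages: v = 1.004242 for the constant dose
(mean 0.9942) and v = 1, λ = 0.005897 for the continuous dose (mean 0.7499).
The calibration helpers (`calibrate_constant_dose`, `calibrate_continuous_dose`)
solve these conditions exactly (closed form / Brent root-finding) and are part
of the public API; the frozen numbers above are their output, not hidden
constants.

## Treatment cases

| case | dose | controller | notes |
|------|------|------------|-------|
| 1 | none | none | normal/cancer competition only; immune state frozen at 0 |
| 2 | none | none | adds the immune equation |
| 3a / 3b | constant / continuous | none | chemotherapy alone |
| 4a / 4b | constant / continuous | SMC | |
| 5a / 5b | constant / continuous | SC | |
| 6a–6d | constant (a, c) / continuous (b, d) | both | controller comparison |

The comparison pairs 6a/6c and 6b/6d are nominally distinguished by whether
the controller's effect propagates to all equations; in a coupled simulation
that propagation is always present, so the pairs run the same computation and
are kept as distinct case ids only for addressability.

## Collocation objectives and the GA

Candidate trajectories are degree-n Bernstein sums on [0, τ] (τ = 1) with the
initial conditions pinned into the leading coefficients (the basis satisfies
B_{i,n}(0) = δ_{i0}, so pinning is exact, not approximate). A physical window
of T days is mapped affinely onto [0, τ]; trial derivatives therefore carry a
factor τ/T when compared against per-day model rates. The default order is
n = 10, so the 11 free coefficients per state are matched by the 11-point
collocation grid; the grid is uniform on [0, τ] (the symmetric default).

Each case's error is the mean over the grid of the squared residual of
exactly the equations that case activates. Drug values C(t_i) come from the
dose closed form, not from a fourth approximant. In case 4 the switching gain
ρ and the surface σ are evaluated on the candidate's own values, with the
same sign smoothing as the simulator. In case 5 the cancer trajectory is the
analytic exponential decay — a substitution, not a residual — so its error
contribution is zero by construction and the search space shrinks to the
normal and immune coefficients. Case 1 likewise searches only the normal and
cancer coefficients, since its equations contain no immune terms.

The optimizer is a real-coded GA: tournament selection (size 3), BLX-0.5
blend crossover (rate 0.9), Gaussian mutation (rate 0.1, initial scale 0.1)
whose scale anneals geometrically (factor 0.995 per generation — added so a
continuous coefficient search can converge below 1e−3 rather than stalling at
the fixed mutation scale), elitism of 1, coefficient bounds [−2, 2], defaults
of 100 individuals × 500 generations, seed 42. The starting constant-guess
candidate is injected into the initial population, so the returned best is
never worse than that evaluated guess. Chromosomes are fixed-length (one gene
per free coefficient); variable-length encodings are incompatible with a
fixed-degree basis.

## Numerical choices

* **Integrator.** Classical RK4 with a fixed step (default 10⁻³ day), chosen
  over adaptive stepping so that the sign discontinuity of SMC produces
  bitwise-reproducible trajectories. With the SC closed loop at τ_a = 0.01
  the per-step decay factor is e^(−0.1), well inside RK4's accuracy range;
  exactness tests against the closed form are run at τ_a = 0.1, where the
  accumulated discretization error stays below the 10⁻⁶ tolerance.
* **Nonnegativity clamp.** States are clamped at zero after each step.
  The model is not positivity-preserving under population-independent drug
  kill or aggressive control, and negative cell counts would corrupt the
  controller terms. The clamp is also why trajectory-level SMC statements
  are certified only up to tumor extinction: the pointwise reaching
  inequality σσ' ≤ −η|σ| holds on the unclamped closed loop (verified on
  random-state sweeps), and along simulated trajectories σ decreases until
  x2 reaches the clamp, after which σ tracks the immune level rather than
  converging to zero (with the default immune influx the surface σ = x2 + x3
  has no reachable zero other than the tumor-and-immune-free state).
* **Sign convention and chattering.** sgn(0) = 0; the default boundary-layer
  width is 10⁻³ (saturation surrogate), with a hard-sign mode used by the
  property tests. As the width shrinks the smoothed closed loop converges
  monotonically to the hard-sign one.
* **Elimination metric.** "Eliminated" is not intrinsically defined for an
  exponentially decaying population, so the package uses a configurable
  threshold, default ε = 10⁻³ (0.4% of the initial burden), and reports the
  first time x2 falls below ε and stays below; multi-day elimination figures
  quoted in the literature for comparable scenarios are treated as upper
  bounds, not equalities. Every report prints the threshold used.
* **Blow-up guard.** Any state magnitude beyond 10⁶ aborts integration with
  a diagnostic rather than silently overflowing.

## Problem sizes used by the shipped checks

The end-to-end checks run the full 100-day scenarios at step 10⁻³ (10⁵ RK4
steps); oracle sweeps use 1–3-day windows, which suffice because the SC
closed loop reaches the elimination threshold within a fraction of a day and
the certified properties are pointwise. The GA cross-check of case 1 runs at
order n = 6 on a 5-day window with 100 × 300 evaluations.

## What the synthetic fixtures do and do not show

The fixture generator produces manufactured Bernstein candidates (exact
ground truths for the objective and recovery tests), noise-perturbed
trajectories (metric robustness), and random state sweeps in [0,1]³ × [0,2]
(controller inequalities). These exercise the mathematics of the model and
controllers; they do not validate the biology. In particular, the default
parameter set is a normalized literature convention, not a fit to patient
data; passing tests demonstrate correctness of the stated model and control
laws, not clinical efficacy of the schedules.

## Known limitations

* The sliding-mode elimination time is sensitive to the online gain ρ, which
  with the default ∂ = 1 is dominated by the immune influx term; published
  day counts for SMC scenarios vary widely, and this implementation makes no
  claim about matching any particular one — only the SC-faster-than-SMC
  ordering is asserted.
* The analytic SC elimination time at τ_a = 0.01 is hours, not days; reported
  multi-day figures for the same configuration are treated as loose upper
  bounds (see the elimination metric above).
* No pharmacokinetic compartments, no pulsed dosing, no actuator saturation,
  no controllers on the normal or immune equations, no stochastic
  patient-level variation.
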