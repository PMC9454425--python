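# tumorctl

Closed-loop simulation of chemo-immunotherapy for a growing tumor, with two
nonlinear feedback controllers acting as drug laws, and a Bernstein-polynomial
collocation solver tuned by a genetic algorithm.

The package is for researchers in mathematical oncology and control who want a
tested, scriptable implementation of the tumor–immune–drug competition model
and of the two drug-scheduling controllers — sliding-mode control (SMC) and
synergetic control (SC) — so that treatment scenarios ("cases") can be
simulated, compared and reproduced from the command line or from Python.

## The model

Four coupled states: normal cells `x1`, cancer cells `x2`, immune cells `x3`
(normalized to the carrying-capacity scale) and drug concentration `C`:

```
x1' = a2 x1 (1 − d2 x1) − e4 x2 x1 − r3 C
x2' = a1 x2 (1 − d1 x2) − e2 x2 x3 − e3 x2 x1 − r2 C + μ
x3' = α + p x3 x2 / (s + x2) − e1 x3 x2 − f1 x3 − r1 C
C'  = vc(t) − f2 C
```

with initial state `(x1, x2, x3, C)(0) = (0.9, 0.25, 0.25, 0)`. The drug kill
terms enter as plain `−r C` (population-independent), and the infusion rate
`vc(t)` is either constant or exponentially decaying ("continuous" dosing).
The control input `μ` acts only on the cancer equation.

**Sliding-mode control** drives the surface `σ = m1 x2 + x3` to zero with
`μ = −ρ sgn(σ) − ∂ a1 x2 (1 − d1 x2)`, where the switching gain `ρ` is
estimated online from the model terms so that the reaching condition
`σ σ' ≤ −η |σ|` holds; a boundary-layer smoothing of `sgn` suppresses
chattering under fixed-step integration.

**Synergetic control** forces the macro-variable `ψ = m2 x2` onto the manifold
`ψ' + ψ/τ_a = 0`. Solving for `μ` cancels every model term in the cancer
equation and leaves exactly `x2' = −x2/τ_a`, i.e. exponential tumor decay
`x2(t) = x2(0) e^(−t/τ_a)` with Lyapunov certificate `L = ψ²/2 = L(0) e^(−2t/τ_a)`.

Candidate trajectories can also be represented as degree-`n` Bernstein
polynomial sums with the initial conditions pinned into the leading
coefficients; the free coefficients are tuned by a real-coded genetic
algorithm minimizing the mean squared collocation residual of the governing
equations over an 11-point grid (`E = Ex1 + Ex2 + Ex3`), case by case.

## Worked example

Compare both controllers under constant-dose chemotherapy (case 6a):

```
$ tumorctl compare --case 6a --horizon 5 --step 1e-3
{
  "case": "6a",
  "horizon": 5.0,
  "step": 0.001,
  "threshold": 0.001,
  "metrics": {
    "elimination_time_smc": 0.878,
    "min_x1_smc": 0.8663853113725042,
    "elimination_time_sc": 0.056,
    "min_x1_sc": 0.8928625498819378,
    "sc_faster": 1.0
  }
}
```

The synergetic controller (τ_a = 0.01) pushes the cancer population below the
elimination threshold 1e−3 in 0.056 days — in agreement with the analytic
prediction τ_a·ln(0.25/10⁻³) ≈ 0.0552 — while the sliding-mode controller
needs 0.878 days; under both laws the normal-cell level never drops below
0.86, well above the 0.75 safety floor.

Sweeping the synergetic convergence time constant:

```
$ tumorctl sweep-tau --values 0.01,0.04,0.07,0.1,0.2 --horizon 40
 tau_a  analytic_days  simulated_days
  0.01       0.055215           0.056
  0.04       0.220858           0.221
  0.07       0.386502           0.387
  0.10       0.552146           0.553
  0.20       1.104292           1.105
```

Elimination time grows linearly in τ_a and the simulated times track the
closed-form inversion to the sampling resolution.

Other entry points: `tumorctl simulate --case 5a --out traj.csv` (single
scenario to CSV), `tumorctl fit --case 1 --order 6 --pop 100 --gens 300`
(GA-tuned Bernstein fit), `tumorctl plot traj.csv --out traj.png`.
Every command accepts `--config run.yaml` with a validated schema
(unknown keys are rejected); see `tumorctl.config`.

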