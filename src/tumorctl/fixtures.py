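"""Seeded synthetic-input generator for tests and examples.

Three kinds of fixture:

* ``exact_solution_approximant`` — a Bernstein candidate whose value and
  derivative profile is known exactly (random coefficients with pinned
  initial conditions), usable as a manufactured ground truth.
* ``perturbed_trajectory`` — a noisy copy of a clean closed-loop
  trajectory, for exercising the outcome metrics.
* ``random_state_sweep`` — random system states in the documented box
  [0,1]^3 x [0,2], for controller-inequality sweeps.

All fixtures are fully determined by the seed.
"""

from __future__ import annotations

import numpy as np

from .bernstein import Approximant, pin_initial_coefficients
from .model import SystemState

KINDS = ("exact_solution_approximant", "perturbed_trajectory", "random_state_sweep")


def generate_fixture(kind: str, seed: int, **kwargs):
    if kind not in KINDS:
        raise ValueError(f"unknown fixture kind {kind!r}; valid: {KINDS}")
    rng = np.random.default_rng(seed)
    if kind == "exact_solution_approximant":
        n = kwargs.get("n", 6)
        spread = kwargs.get("spread", 0.5)
        a = Approximant(n=n, tau=kwargs.get("tau", 1.0),
                        f=0.9 + spread * rng.standard_normal(n + 1),
                        g=0.25 + spread * rng.standard_normal(n + 1),
                        h=0.25 + spread * rng.standard_normal(n + 1))
        return pin_initial_coefficients(a)
    if kind == "perturbed_trajectory":
        from .simulation import Trajectory

        base: Trajectory = kwargs["base"]
        noise = kwargs.get("noise", 1e-3)
        states = base.states + noise * rng.standard_normal(base.states.shape)
        return Trajectory(times=base.times.copy(), states=np.clip(states, 0.0, None),
                          controls=base.controls.copy(), source=base.source)
    # random_state_sweep
    count = kwargs.get("count", 1000)
    cells = rng.uniform(0.0, 1.0, size=(count, 3))
    conc = rng.uniform(0.0, 2.0, size=count)
    return [SystemState(t=0.0, x1=c[0], x2=c[1], x3=c[2], C=u)
            for c, u in zip(cells, conc)]
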