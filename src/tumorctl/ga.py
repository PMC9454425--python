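"""Real-coded genetic algorithm over the free Bernstein coefficients.

One gene per free coefficient (the pinned initial-condition entries and
any analytically substituted state are excluded from the chromosome).
Operators: tournament selection, blend (BLX-alpha) crossover, Gaussian
mutation with a geometrically annealed step size, and elitism, which
makes the best-fitness history nonincreasing.  All randomness flows
from a single seed, so identical configurations reproduce bitwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace

import numpy as np

from .bernstein import Approximant, pin_initial_coefficients
from .objectives import FREE_STATES, case_error, total_error


@dataclass(frozen=True)
class GAConfig:
    population_size: int = 100
    generations: int = 500
    crossover_rate: float = 0.9
    mutation_rate: float = 0.1
    mutation_scale: float = 0.1
    mutation_decay: float = 0.995
    blend_alpha: float = 0.5
    tournament_size: int = 3
    coefficient_bounds: tuple[float, float] = (-2.0, 2.0)
    elitism_count: int = 1
    seed: int = 42

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if not (0 <= self.crossover_rate <= 1 and 0 <= self.mutation_rate <= 1):
            raise ValueError("rates must lie in [0, 1]")
        if not 1 <= self.elitism_count < self.population_size:
            raise ValueError("elitism_count must be in [1, population_size)")
        lo, hi = self.coefficient_bounds
        if not lo < hi:
            raise ValueError("coefficient_bounds must be an increasing pair")
        if self.generations < 1 or self.tournament_size < 1:
            raise ValueError("generations and tournament_size must be >= 1")


@dataclass
class GAResult:
    best_coefficients: Approximant
    best_fitness: float
    history: np.ndarray
    best_vector: np.ndarray = field(default=None)


# --- chromosome encoding ----------------------------------------------------

def free_coefficient_slots(n: int, states: tuple[str, ...]) -> list[tuple[str, int]]:
    """(state, index) pairs searched by the GA: indices 1..n of each
    selected state (index 0 is pinned to the initial condition)."""
    return [(w, i) for w in states for i in range(1, n + 1)]


def vector_to_approximant(vec: np.ndarray, pinned: Approximant,
                          states: tuple[str, ...]) -> Approximant:
    arrs = {"x1": pinned.f.copy(), "x2": pinned.g.copy(), "x3": pinned.h.copy()}
    k = 0
    for w in states:
        arrs[w][1:] = vec[k:k + pinned.n]
        k += pinned.n
    return dc_replace(pinned, f=arrs["x1"], g=arrs["x2"], h=arrs["x3"])


def approximant_to_vector(a: Approximant, states: tuple[str, ...]) -> np.ndarray:
    return np.concatenate([a.coefficients(w)[1:] for w in states])


# --- the optimizer ----------------------------------------------------------

def ga_optimize(objective, pinned: Approximant, cfg: GAConfig,
                states: tuple[str, ...] = ("x1", "x2", "x3")) -> GAResult:
    """Minimize ``objective(approximant)`` over the free coefficients.

    The pinned entries (f0, g0, h0) are never touched; non-finite
    objective values are treated as worst fitness.  Returns the best
    individual ever evaluated together with the per-generation best
    history (nonincreasing under elitism).
    """
    pinned = pin_initial_coefficients(pinned)
    dim = pinned.n * len(states)
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.coefficient_bounds

    def evaluate(vec: np.ndarray) -> float:
        val = objective(vector_to_approximant(vec, pinned, states))
        return float(val) if np.isfinite(val) else np.inf

    pop = rng.uniform(lo, hi, size=(cfg.population_size, dim))
    # seed the search with the pinned starting guess so the result is
    # never worse than an evaluated member of the initial population
    pop[0] = np.clip(approximant_to_vector(pinned, states), lo, hi)
    fit = np.array([evaluate(v) for v in pop])
    history = []
    scale = cfg.mutation_scale

    for _gen in range(cfg.generations):
        order = np.argsort(fit)
        elites = pop[order[: cfg.elitism_count]].copy()
        elite_fit = fit[order[: cfg.elitism_count]].copy()

        children = []
        while len(children) < cfg.population_size - cfg.elitism_count:
            # tournament selection of two parents
            parents = []
            for _ in range(2):
                idx = rng.integers(0, cfg.population_size, size=cfg.tournament_size)
                parents.append(pop[idx[np.argmin(fit[idx])]].copy())
            p1, p2 = parents
            if rng.random() < cfg.crossover_rate:
                # BLX-alpha: sample uniformly in the expanded parent box
                cmin = np.minimum(p1, p2)
                cmax = np.maximum(p1, p2)
                span = cmax - cmin
                low = cmin - cfg.blend_alpha * span
                high = cmax + cfg.blend_alpha * span
                p1 = rng.uniform(low, high)
                p2 = rng.uniform(low, high)
            for child in (p1, p2):
                mask = rng.random(dim) < cfg.mutation_rate
                if mask.any():
                    child[mask] += rng.normal(0.0, scale, size=int(mask.sum()))
                children.append(np.clip(child, lo, hi))
        children = np.asarray(children[: cfg.population_size - cfg.elitism_count])
        child_fit = np.array([evaluate(v) for v in children])

        pop = np.vstack([elites, children])
        fit = np.concatenate([elite_fit, child_fit])
        history.append(float(fit.min()))
        scale *= cfg.mutation_decay

    best_idx = int(np.argmin(fit))
    best_vec = pop[best_idx]
    return GAResult(
        best_coefficients=vector_to_approximant(best_vec, pinned, states),
        best_fitness=float(fit[best_idx]),
        history=np.asarray(history),
        best_vector=best_vec.copy(),
    )


def solve_case(case_id: int, params, dose=None, ctrl=None,
               ga_cfg: GAConfig | None = None, n: int = 10,
               horizon: float = 100.0, grid=None):
    """Run the GA on one case's collocation error and evaluate the best
    candidate on a dense time grid.

    Returns ``(GAResult, Trajectory)``; for case 5 the emitted cancer
    trajectory is the analytic exponential decay (substituted, not
    searched).
    """
    from .simulation import trajectory_from_approximant

    ga_cfg = ga_cfg or GAConfig()
    states = FREE_STATES[case_id]
    pinned = pin_initial_coefficients(Approximant.constant(n))

    def objective(a: Approximant) -> float:
        return total_error(case_error(case_id, a, params, dose=dose, ctrl=ctrl,
                                      grid=grid, horizon=horizon))

    result = ga_optimize(objective, pinned, ga_cfg, states=states)
    traj = trajectory_from_approximant(result.best_coefficients, horizon,
                                       case_id=case_id, ctrl=ctrl, params=params,
                                       dose=dose)
    return result, traj
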