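"""Bernstein basis polynomials and the three-state trial solutions.

The degree-n Bernstein basis on [0, tau],

    B_{i,n}(t) = C(n,i) t^i (tau-t)^(n-i) / tau^n,

is nonnegative and forms a partition of unity, and satisfies the
endpoint selection B_{i,n}(0) = delta_{i0}, B_{i,n}(tau) = delta_{in}.
Its derivative telescopes into the degree-(n-1) basis,

    d/dt B_{i,n} = (n/tau) (B_{i-1,n-1} - B_{i,n-1}),

with out-of-range indices contributing zero.  Candidate trajectories for
the three cell populations are coefficient-weighted basis sums whose
leading coefficients are pinned to the initial conditions (B_{i,n}(0)
selects exactly the i=0 coefficient).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from math import comb

import numpy as np

_STATES = ("x1", "x2", "x3")
_COEFF_NAME = {"x1": "f", "x2": "g", "x3": "h"}

#: Initial conditions pinned into the leading coefficients (f0, g0, h0).
PINNED_INITIAL = {"x1": 0.9, "x2": 0.25, "x3": 0.25}


def _check_args(i: int, n: int, t: float, tau: float) -> None:
    if n < 0:
        raise ValueError(f"order n must be >= 0, got {n}")
    if tau <= 0:
        raise ValueError(f"tau must be > 0, got {tau}")
    if not 0 <= i <= n:
        raise ValueError(f"index i={i} out of range 0..{n}")
    if not 0.0 <= t <= tau * (1 + 1e-12):
        raise ValueError(f"t={t} outside [0, {tau}]")


def basis_value(i: int, n: int, t: float, tau: float = 1.0) -> float:
    """B_{i,n}(t) on [0, tau]."""
    _check_args(i, n, t, tau)
    return comb(n, i) * t**i * (tau - t) ** (n - i) / tau**n


def basis_derivative(i: int, n: int, t: float, tau: float = 1.0) -> float:
    """d/dt B_{i,n}(t) via the telescoping identity.

    (n/tau) * (B_{i-1,n-1}(t) - B_{i,n-1}(t)); B terms with index outside
    0..n-1 are zero.
    """
    _check_args(i, n, t, tau)
    left = basis_value(i - 1, n - 1, t, tau) if 1 <= i <= n else 0.0
    right = basis_value(i, n - 1, t, tau) if i <= n - 1 else 0.0
    return n / tau * (left - right)


def de_casteljau_basis(i: int, n: int, t: float) -> float:
    """B_{i,n}(t) on [0,1] by the de Casteljau degree recursion
    B_{i,n} = (1-t) B_{i,n-1} + t B_{i-1,n-1}.  Test oracle."""
    if n == 0:
        return 1.0 if i == 0 else 0.0
    if i < 0 or i > n:
        return 0.0
    return (1.0 - t) * de_casteljau_basis(i, n - 1, t) + t * de_casteljau_basis(i - 1, n - 1, t)


@dataclass(frozen=True)
class Approximant:
    """Bernstein trial solution: coefficient vectors f, g, h (length n+1)
    for the normal, cancer and immune populations on [0, tau]."""

    n: int
    tau: float
    f: np.ndarray
    g: np.ndarray
    h: np.ndarray

    def __post_init__(self) -> None:
        for name in ("f", "g", "h"):
            arr = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, arr)
            if arr.shape != (self.n + 1,):
                raise ValueError(f"{name} must have length n+1={self.n + 1}, got {arr.shape}")
        if self.tau <= 0:
            raise ValueError("tau must be > 0")

    def coefficients(self, which: str) -> np.ndarray:
        if which not in _STATES:
            raise ValueError(f"selector must be one of {_STATES}, got {which!r}")
        return {"x1": self.f, "x2": self.g, "x3": self.h}[which]

    @classmethod
    def constant(cls, n: int, tau: float = 1.0,
                 values: tuple[float, float, float] = (0.9, 0.25, 0.25)) -> "Approximant":
        return cls(n=n, tau=tau,
                   f=np.full(n + 1, values[0]),
                   g=np.full(n + 1, values[1]),
                   h=np.full(n + 1, values[2]))

    def to_json(self) -> str:
        return json.dumps({"n": self.n, "tau": self.tau,
                           "f": self.f.tolist(), "g": self.g.tolist(),
                           "h": self.h.tolist()})

    @classmethod
    def from_json(cls, text: str) -> "Approximant":
        d = json.loads(text)
        return cls(n=d["n"], tau=d["tau"],
                   f=np.asarray(d["f"]), g=np.asarray(d["g"]), h=np.asarray(d["h"]))


def approx_value(a: Approximant, which: str, t: float) -> float:
    """Coefficient-weighted basis sum of one state at time t in [0, tau]."""
    c = a.coefficients(which)
    return float(sum(c[i] * basis_value(i, a.n, t, a.tau) for i in range(a.n + 1)))


def approx_derivative(a: Approximant, which: str, t: float) -> float:
    """Time derivative of one state's trial solution at t.

    Telescoped form (n/tau)(sum_i c_i B_{i-1,n-1} - sum_i c_i B_{i,n-1}),
    identical to the coefficient-weighted sum of basis derivatives.
    """
    c = a.coefficients(which)
    n, tau = a.n, a.tau
    left = sum(c[i] * basis_value(i - 1, n - 1, t, tau) for i in range(1, n + 1))
    right = sum(c[i] * basis_value(i, n - 1, t, tau) for i in range(0, n))
    return float(n / tau * (left - right))


def pin_initial_coefficients(a: Approximant) -> Approximant:
    """Return a copy with the leading coefficients pinned to the initial
    conditions (f0=0.9, g0=0.25, h0=0.25).  Idempotent; the pinned
    entries are excluded from any coefficient search."""
    f, g, h = a.f.copy(), a.g.copy(), a.h.copy()
    f[0] = PINNED_INITIAL["x1"]
    g[0] = PINNED_INITIAL["x2"]
    h[0] = PINNED_INITIAL["x3"]
    return replace(a, f=f, g=g, h=h)


def elevate_degree(a: Approximant) -> Approximant:
    """Re-express an order-n approximant at order n+1 (identical values
    everywhere on [0, tau]); standard degree-elevation coefficients."""
    n = a.n

    def lift(c: np.ndarray) -> np.ndarray:
        out = np.empty(n + 2)
        out[0] = c[0]
        out[n + 1] = c[n]
        for i in range(1, n + 1):
            out[i] = i / (n + 1) * c[i - 1] + (1 - i / (n + 1)) * c[i]
        return out

    return Approximant(n=n + 1, tau=a.tau, f=lift(a.f), g=lift(a.g), h=lift(a.h))
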