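"""Drug-law feedback controllers on the cancer-cell equation.

Two controllers act through the additive input mu on dx2/dt:

* Sliding-mode control (SMC).  A sliding surface sigma = m1*x2 + x3 is
  driven to zero by a discontinuous law
  mu = -rho*sgn(sigma) - partial*a1*x2*(1 - d1*x2), where the switching
  gain rho is estimated online from the model terms so that the reaching
  condition sigma*dsigma/dt <= -eta*|sigma| holds.  The hard sign
  induces chattering under fixed-step integration, so a boundary-layer
  (saturation) surrogate of configurable width is available.

* Synergetic control (SC).  A macro-variable psi = m2*(x2 - x2_ref)
  (reference 0) is forced to obey the manifold dpsi/dt + psi/tau_a = 0.
  Solving for mu cancels every model term in the cancer equation and
  leaves dx2/dt = -x2/tau_a, i.e. exact exponential tumor decay
  x2(t) = x2(0) e^(-t/tau_a) with no switching.  The Lyapunov function
  L = psi^2 / 2 then decays as L(0) e^(-2t/tau_a).

The control input is a signed correction term on the cancer equation,
not a physical infusion rate: its nonnegativity is deliberately NOT
enforced.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .model import ModelParams, SystemState


@dataclass(frozen=True)
class SMCConfig:
    """Sliding-mode gains: growth-reduction coefficient ``partial`` in
    [0,1], surface slope m1 > 0, reaching rate eta >= 0, and the
    boundary-layer ``smoothing_width`` (0 = hard sign)."""

    partial: float = 1.0
    m1: float = 1.0
    eta: float = 0.0
    smoothing_width: float = 1e-3
    rho_override: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.partial <= 1.0:
            raise ValueError("partial must lie in [0, 1]")
        if self.m1 <= 0:
            raise ValueError("m1 must be > 0")
        if self.eta < 0 or self.smoothing_width < 0:
            raise ValueError("eta and smoothing_width must be >= 0")


@dataclass(frozen=True)
class SCConfig:
    """Synergetic gains: macro-variable slope m2 > 0, convergence time
    constant tau_a > 0 (days), and the cancer reference level (0)."""

    m2: float = 1.0
    tau_a: float = 0.01
    x2_ref: float = 0.0

    def __post_init__(self) -> None:
        if self.m2 <= 0 or self.tau_a <= 0:
            raise ValueError("m2 and tau_a must be > 0")


def sgn(x: float, width: float = 0.0) -> float:
    """Sign with sgn(0)=0; for width > 0 a saturation surrogate equal to
    x/width inside the boundary layer and +/-1 outside."""
    if width > 0:
        return max(-1.0, min(1.0, x / width))
    return math.copysign(1.0, x) if x != 0.0 else 0.0


def sliding_surface(state: SystemState, cfg: SMCConfig) -> float:
    """sigma = m1*x2 + x3."""
    return cfg.m1 * state.x2 + state.x3


def smc_gain_rho(state: SystemState, params: ModelParams, cfg: SMCConfig) -> float:
    """Online switching-gain estimate.

    rho = (|m1*((1-partial)*a1*x2*(1-d1*x2) - e2*x3*x2 - e3*x2*x1 - r2*C)
            + alpha + p*x3*x2/(s+x2) - e1*x3*x2 - f1*x3 - r1*C| + eta) / m1,

    the smallest gain certifying the reaching condition with margin eta.
    """
    p = params
    x1, x2, x3, C = state.x1, state.x2, state.x3, state.C
    drift = (
        cfg.m1 * ((1.0 - cfg.partial) * p.a1 * x2 * (1.0 - p.d1 * x2)
                  - p.e2 * x3 * x2 - p.e3 * x2 * x1 - p.r2 * C)
        + p.alpha + p.p * x3 * x2 / (p.s + x2)
        - p.e1 * x3 * x2 - p.f1 * x3 - p.r1 * C
    )
    return (abs(drift) + cfg.eta) / cfg.m1


def smc_control(state: SystemState, params: ModelParams, cfg: SMCConfig,
                hard_sign: bool = False) -> float:
    """SMC drug law mu = -rho*sgn(sigma) - partial*a1*x2*(1 - d1*x2).

    rho comes from :func:`smc_gain_rho` unless ``rho_override`` is set.
    ``hard_sign`` forces the discontinuous sign regardless of the
    configured boundary-layer width.
    """
    rho = cfg.rho_override if cfg.rho_override is not None else smc_gain_rho(state, params, cfg)
    sigma = sliding_surface(state, cfg)
    width = 0.0 if hard_sign else cfg.smoothing_width
    x2 = state.x2
    return -rho * sgn(sigma, width) - cfg.partial * params.a1 * x2 * (1.0 - params.d1 * x2)


def reaching_margin(state: SystemState, params: ModelParams, cfg: SMCConfig) -> float:
    """sigma * dsigma/dt along the hard-sign closed loop.

    dsigma/dt = m1*dx2 + dx3 with the SMC substituted into the cancer
    equation; with the online gain the contract is
    sigma*dsigma/dt <= -eta*|sigma| <= 0.
    """
    p = params
    x1, x2, x3, C = state.x1, state.x2, state.x3, state.C
    sigma = sliding_surface(state, cfg)
    rho = cfg.rho_override if cfg.rho_override is not None else smc_gain_rho(state, params, cfg)
    dx2_closed = ((1.0 - cfg.partial) * p.a1 * x2 * (1.0 - p.d1 * x2)
                  - rho * sgn(sigma)
                  - p.e2 * x3 * x2 - p.e3 * x2 * x1 - p.r2 * C)
    dx3 = p.alpha + p.p * x3 * x2 / (p.s + x2) - p.e1 * x3 * x2 - p.f1 * x3 - p.r1 * C
    return sigma * (cfg.m1 * dx2_closed + dx3)


def sc_macro_variable(state: SystemState, cfg: SCConfig) -> float:
    """psi = m2 * (x2 - x2_ref)."""
    return cfg.m2 * (state.x2 - cfg.x2_ref)


def sc_control(state: SystemState, params: ModelParams, cfg: SCConfig) -> float:
    """SC drug law mu = -a1*x2*(1-d1*x2) + e2*x2*x3 + e3*x2*x1 + r2*C - x2/tau_a.

    Substituted into the cancer equation every model term cancels,
    leaving dx2/dt = -x2/tau_a.
    """
    p = params
    x1, x2, x3, C = state.x1, state.x2, state.x3, state.C
    return (-p.a1 * x2 * (1.0 - p.d1 * x2) + p.e2 * x2 * x3 + p.e3 * x2 * x1
            + p.r2 * C - x2 / cfg.tau_a)


def sc_closed_form_x2(t: float, x2_0: float = 0.25, tau_a: float = 0.01) -> float:
    """Exact cancer trajectory under SC: x2(t) = x2(0) e^(-t/tau_a)."""
    if t < 0:
        raise ValueError(f"t must be >= 0, got {t}")
    return x2_0 * math.exp(-t / tau_a)


def lyapunov_value(psi: float) -> float:
    """L = psi^2 / 2."""
    return 0.5 * psi * psi


def lyapunov_closed_form(t: float, L0: float, tau_a: float) -> float:
    """L(t) = L(0) e^(-2t/tau_a) along the SC closed loop."""
    if t < 0:
        raise ValueError(f"t must be >= 0, got {t}")
    return L0 * math.exp(-2.0 * t / tau_a)
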