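"""Tumor-immune-chemotherapy ODE model.

Four coupled states: normal cells x1, cancer cells x2, immune cells x3
(all normalized to the carrying-capacity scale) and drug concentration C.
The cell equations follow the De Pillis-Radunskaya competition form with
logistic growth for x1/x2, a Michaelis-Menten immune recruitment term for
x3, and first-order drug kill terms.  The drug obeys a one-compartment
balance dC/dt = vc(t) - f2*C driven by a constant or exponentially
decaying infusion rate.

Note the drug kill terms enter as plain -r*C (not mass-action -r*C*x):
the kill rate is independent of the target population size.  This is the
model form implemented throughout; it makes x = 0 absorbing only through
the nonnegativity clamp applied by the integrator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields


@dataclass(frozen=True)
class ModelParams:
    """Rate constants of the four-state model, in normalized units (1/day).

    Defaults are the standard normalized competition-model constants;
    every value is configurable and nothing downstream hard-codes them.

    Attributes
    ----------
    a1, a2 : logistic growth rates of cancer and normal cells.
    d1, d2 : inverse carrying capacities of cancer and normal cells.
    e1..e4 : competition/kill cross terms (e1: immune loss per cancer
        encounter, e2: cancer kill by immunes, e3: cancer loss to
        normals, e4: normal loss to cancers).
    r1, r2, r3 : drug kill coefficients for immune, cancer and normal
        cells respectively.
    f1 : natural immune death rate;  f2 : drug washout rate.
    alpha : constant immune influx;  p, s : immune recruitment response
        rate and half-saturation threshold.
    """

    a1: float = 1.5
    a2: float = 1.0
    d1: float = 1.0
    d2: float = 1.0
    e1: float = 1.0
    e2: float = 0.5
    e3: float = 1.0
    e4: float = 1.0
    r1: float = 0.2
    r2: float = 0.3
    r3: float = 0.1
    f1: float = 0.2
    f2: float = 1.0
    alpha: float = 0.33
    p: float = 0.01
    s: float = 0.3

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"ModelParams.{f.name} must be finite and >= 0, got {v}")
        for name in ("d1", "d2", "s", "f2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"ModelParams.{name} must be > 0")


@dataclass
class SystemState:
    """One sample (t, x1, x2, x3, C) of the closed-loop system."""

    t: float
    x1: float
    x2: float
    x3: float
    C: float

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.x1, self.x2, self.x3, self.C)


def initial_state() -> SystemState:
    """Untreated-patient initial condition.

    x1(0)=0.9, x2(0)=0.25, x3(0)=0.25; the drug concentration starts at
    zero (treatment begins at t=0).  The cancer level 0.25 is the
    patient threshold the scenarios start from.
    """
    return SystemState(t=0.0, x1=0.9, x2=0.25, x3=0.25, C=0.0)


# --- dose schedules ---------------------------------------------------------

#: Constant-dose amplitude calibrated so the 100-day mean concentration
#: under the default washout f2=1 is 0.9942.
DEFAULT_CONSTANT_V = 1.004242
#: Continuous (exponentially decaying) dose: amplitude 1 and decay rate
#: calibrated so the 100-day mean concentration is 0.7499.
DEFAULT_CONTINUOUS_V = 1.0
DEFAULT_CONTINUOUS_LAMBDA = 0.005897


@dataclass(frozen=True)
class DoseSchedule:
    """Chemotherapy infusion rate vc(t).

    mode "constant": vc(t) = v for all t.
    mode "continuous_exponential": vc(t) = v * exp(-lam * t), an
    exponentially tapering infusion ("continuous" dosing).
    """

    mode: str = "constant"
    v: float = DEFAULT_CONSTANT_V
    lam: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in ("constant", "continuous_exponential"):
            raise ValueError(f"unknown dose mode {self.mode!r}")
        if self.v < 0 or self.lam < 0:
            raise ValueError("dose amplitude and decay rate must be >= 0")

    @classmethod
    def constant(cls, v: float = DEFAULT_CONSTANT_V) -> "DoseSchedule":
        return cls(mode="constant", v=v)

    @classmethod
    def continuous(
        cls,
        v: float = DEFAULT_CONTINUOUS_V,
        lam: float = DEFAULT_CONTINUOUS_LAMBDA,
    ) -> "DoseSchedule":
        return cls(mode="continuous_exponential", v=v, lam=lam)

    @classmethod
    def none(cls) -> "DoseSchedule":
        return cls(mode="constant", v=0.0)


def dose_rate(schedule: DoseSchedule, t: float) -> float:
    """Infusion rate vc(t) of a schedule at time t (days)."""
    if t < 0:
        raise ValueError(f"t must be >= 0, got {t}")
    if schedule.mode == "constant":
        return schedule.v
    return schedule.v * math.exp(-schedule.lam * t)


def concentration_closed_form(schedule: DoseSchedule, params: ModelParams, t: float) -> float:
    """Drug concentration C(t) from C(0)=0 under a schedule, analytically.

    Solves dC/dt = vc(t) - f2*C.  Constant dose: C = (v/f2)(1-e^(-f2 t));
    exponential dose: C = v/(f2-lam) (e^(-lam t) - e^(-f2 t)) (confluent
    limit v*t*e^(-f2 t) when lam == f2).
    """
    if t < 0:
        raise ValueError(f"t must be >= 0, got {t}")
    f2, v = params.f2, schedule.v
    if schedule.mode == "constant":
        return (v / f2) * (1.0 - math.exp(-f2 * t))
    lam = schedule.lam
    if math.isclose(lam, f2, rel_tol=1e-12, abs_tol=1e-15):
        return v * t * math.exp(-f2 * t)
    return v / (f2 - lam) * (math.exp(-lam * t) - math.exp(-f2 * t))


def mean_concentration_closed_form(
    schedule: DoseSchedule, params: ModelParams, horizon: float
) -> float:
    """Exact time-average of C(t) over [0, horizon] from C(0)=0."""
    from scipy.integrate import quad

    val, _ = quad(lambda t: concentration_closed_form(schedule, params, t), 0.0, horizon,
                  limit=200)
    return val / horizon


def calibrate_constant_dose(
    target_mean: float, params: ModelParams | None = None, horizon: float = 100.0
) -> float:
    """Amplitude v for which the constant-dose mean concentration over
    [0, horizon] equals ``target_mean`` (closed form; no search needed)."""
    p = params or ModelParams()
    f2 = p.f2
    factor = (1.0 / f2) * (1.0 - (1.0 - math.exp(-f2 * horizon)) / (f2 * horizon))
    return target_mean / factor


def calibrate_continuous_dose(
    target_mean: float,
    params: ModelParams | None = None,
    horizon: float = 100.0,
    v: float = 1.0,
) -> float:
    """Decay rate lam for which the exponential-dose mean concentration
    over [0, horizon] equals ``target_mean`` at fixed amplitude v."""
    from scipy.optimize import brentq

    p = params or ModelParams()

    def err(lam: float) -> float:
        sched = DoseSchedule(mode="continuous_exponential", v=v, lam=lam)
        return mean_concentration_closed_form(sched, p, horizon) - target_mean

    return brentq(err, 1e-8, 1.0, xtol=1e-12)


# --- right-hand side --------------------------------------------------------

def tumor_rhs(
    state: SystemState,
    params: ModelParams,
    dose: float = 0.0,
    mu: float = 0.0,
) -> tuple[float, float, float, float]:
    """Time derivatives (dx1, dx2, dx3, dC) of the coupled model.

    ``dose`` is the instantaneous infusion rate vc(t); ``mu`` is the
    control input added to the cancer-cell equation (mu = 0 recovers the
    open-loop model).
    """
    x1, x2, x3, C = state.x1, state.x2, state.x3, state.C
    for name, v in (("x1", x1), ("x2", x2), ("x3", x3), ("C", C),
                    ("dose", dose), ("mu", mu)):
        if not math.isfinite(v):
            raise ValueError(f"non-finite input {name}={v}")
    p = params
    dx1 = p.a2 * x1 * (1.0 - p.d2 * x1) - p.e4 * x2 * x1 - p.r3 * C
    dx2 = p.a1 * x2 * (1.0 - p.d1 * x2) - p.e2 * x2 * x3 - p.e3 * x2 * x1 - p.r2 * C + mu
    dx3 = p.alpha + p.p * x3 * x2 / (p.s + x2) - p.e1 * x3 * x2 - p.f1 * x3 - p.r1 * C
    dC = dose - p.f2 * C
    return (dx1, dx2, dx3, dC)
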