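"""Collocation residual error functions for the five treatment cases.

A candidate Bernstein trajectory is scored by the mean squared residual
of the governing equations over a fixed grid of 11 collocation points.
The five cases activate progressively more of the model:

1. normal + cancer competition only (no immunes, no drug);
2. adds the immune equation (immunotherapy, no drug);
3. adds chemotherapy (drug kill terms, C from the dose closed form);
4. case 3 with the sliding-mode drug law substituted into the cancer
   residual (switching gain evaluated on the candidate trajectory);
5. case 3 with the synergetic closed loop: the cancer trajectory is the
   analytic exponential decay (substituted, not searched), so its
   residual is zero by construction and only the normal/immune
   coefficients remain free.

The trial functions live on [0, tau]; a simulation window of T days is
mapped affinely onto it, so trial derivatives pick up a factor tau/T
when compared against the per-day model rates.

The combined objective minimized by the GA is the plain sum
E = Ex1 + Ex2 + Ex3.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bernstein import Approximant, approx_derivative, approx_value
from .controllers import SCConfig, SMCConfig, sgn
from .model import DoseSchedule, ModelParams, concentration_closed_form

N_COLLOCATION = 11


@dataclass(frozen=True)
class CollocationGrid:
    """Exactly 11 strictly increasing points spanning [0, tau]."""

    points: np.ndarray = field(default_factory=lambda: np.linspace(0.0, 1.0, N_COLLOCATION))
    tau: float = 1.0

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        object.__setattr__(self, "points", pts)
        if pts.shape != (N_COLLOCATION,):
            raise ValueError(f"grid must have exactly {N_COLLOCATION} points")
        if not np.all(np.diff(pts) > 0):
            raise ValueError("grid points must be strictly increasing")
        if pts[0] != 0.0 or not np.isclose(pts[-1], self.tau):
            raise ValueError(f"grid must span [0, {self.tau}]")

    @classmethod
    def uniform(cls, tau: float = 1.0) -> "CollocationGrid":
        return cls(points=np.linspace(0.0, tau, N_COLLOCATION), tau=tau)


@dataclass(frozen=True)
class ErrorReport:
    """Per-state mean squared residuals and their sum."""

    ex1: float
    ex2: float
    ex3: float = 0.0

    @property
    def total(self) -> float:
        return self.ex1 + self.ex2 + self.ex3


def total_error(report: ErrorReport) -> float:
    """Combined objective E = Ex1 + Ex2 + Ex3 (Ex3 = 0 when absent)."""
    return report.total


VALID_CASES = (1, 2, 3, 4, 5)

#: Coefficient blocks searched by the optimizer in each case.  Case 1
#: has no immune state; case 5 substitutes the analytic cancer decay.
FREE_STATES = {1: ("x1", "x2"), 2: ("x1", "x2", "x3"), 3: ("x1", "x2", "x3"),
               4: ("x1", "x2", "x3"), 5: ("x1", "x3")}


def case_error(
    case_id: int,
    a: Approximant,
    params: ModelParams,
    dose: DoseSchedule | None = None,
    ctrl: SMCConfig | SCConfig | None = None,
    grid: CollocationGrid | None = None,
    horizon: float = 100.0,
) -> ErrorReport:
    """Mean squared collocation residuals of one case for a candidate.

    ``horizon`` is the physical window (days) the trial interval [0, tau]
    represents; drug concentrations are evaluated analytically at the
    mapped physical times.  Cases 4 and 5 require an SMCConfig/SCConfig
    respectively; cases 1-2 ignore the dose.
    """
    if case_id not in VALID_CASES:
        raise ValueError(f"unknown case id {case_id}")
    if case_id == 4 and not isinstance(ctrl, SMCConfig):
        raise ValueError("case 4 requires an SMCConfig")
    if case_id == 5 and not isinstance(ctrl, SCConfig):
        raise ValueError("case 5 requires an SCConfig")
    grid = grid or CollocationGrid.uniform(a.tau)
    p = params
    scale = grid.tau / horizon  # d/dt_phys = scale * d/ds
    with_drug = case_id >= 3
    if with_drug and dose is None:
        dose = DoseSchedule.constant()

    r1 = r2 = r3 = 0.0
    sq = np.zeros(3)
    for s_pt in grid.points:
        t_phys = horizon * s_pt / grid.tau
        x1 = approx_value(a, "x1", s_pt)
        dx1 = approx_derivative(a, "x1", s_pt) * scale
        C = concentration_closed_form(dose, p, t_phys) if with_drug else 0.0
        if case_id == 5:
            from .controllers import sc_closed_form_x2

            x2 = sc_closed_form_x2(t_phys, x2_0=a.g[0], tau_a=ctrl.tau_a)
        else:
            x2 = approx_value(a, "x2", s_pt)
            dx2 = approx_derivative(a, "x2", s_pt) * scale
        if case_id >= 2:
            x3 = approx_value(a, "x3", s_pt)
            dx3 = approx_derivative(a, "x3", s_pt) * scale

        rx1 = dx1 - p.a2 * x1 * (1.0 - p.d2 * x1) + p.e4 * x2 * x1
        if with_drug:
            rx1 += p.r3 * C
        sq[0] += rx1 * rx1

        if case_id == 1:
            rx2 = dx2 - p.a1 * x2 * (1.0 - p.d1 * x2) + p.e3 * x2 * x1
            sq[1] += rx2 * rx2
        elif case_id in (2, 3):
            rx2 = (dx2 - p.a1 * x2 * (1.0 - p.d1 * x2)
                   + p.e2 * x3 * x2 + p.e3 * x2 * x1)
            if with_drug:
                rx2 += p.r2 * C
            sq[1] += rx2 * rx2
        elif case_id == 4:
            from .model import SystemState
            from .controllers import smc_gain_rho

            st = SystemState(t=t_phys, x1=x1, x2=x2, x3=x3, C=C)
            rho = (ctrl.rho_override if ctrl.rho_override is not None
                   else smc_gain_rho(st, p, ctrl))
            sigma = ctrl.m1 * x2 + x3
            rx2 = (dx2 - (1.0 - ctrl.partial) * p.a1 * x2 * (1.0 - p.d1 * x2)
                   + rho * sgn(sigma, ctrl.smoothing_width)
                   + p.e2 * x3 * x2 + p.e3 * x2 * x1 + p.r2 * C)
            sq[1] += rx2 * rx2
        # case 5: cancer residual identically zero (analytic substitution)

        if case_id >= 2:
            rx3 = (dx3 - p.alpha - p.p * x3 * x2 / (p.s + x2)
                   + p.e1 * x3 * x2 + p.f1 * x3)
            if with_drug:
                rx3 += p.r1 * C
            sq[2] += rx3 * rx3

    m = float(len(grid.points))
    ex1, ex2, ex3 = sq / m
    if case_id == 1:
        ex3 = 0.0
    return ErrorReport(ex1=float(ex1), ex2=float(ex2), ex3=float(ex3))
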