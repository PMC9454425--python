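"""Closed-loop numerical integration, treatment-case runner and metrics.

The integrator is a fixed-step classical Runge-Kutta (RK4) scheme.  A
fixed step (rather than adaptive stepping) keeps trajectories bitwise
reproducible in the presence of the sliding-mode sign discontinuity.
Populations and drug concentration are clamped at zero after each step:
the model is not positivity-preserving under aggressive control and
negative cell counts would corrupt the controller terms.

Treatment cases
---------------
=====  ==========================  ==========
case   dose                        controller
=====  ==========================  ==========
1      none                        none (immune state frozen at 0)
2      none                        none
3a/3b  constant / continuous       none
4a/4b  constant / continuous       sliding mode
5a/5b  constant / continuous       synergetic
6a/6c  constant                    both (comparison)
6b/6d  continuous                  both (comparison)
=====  ==========================  ==========
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .controllers import SCConfig, SMCConfig, sc_control, smc_control
from .model import (
    DoseSchedule,
    ModelParams,
    SystemState,
    concentration_closed_form,
    dose_rate,
    initial_state,
)

NOT_ELIMINATED = math.inf
DEFAULT_THRESHOLD = 1e-3
BLOWUP_LIMIT = 1e6


@dataclass
class Trajectory:
    """Time-stamped closed-loop samples plus the applied control."""

    times: np.ndarray
    states: np.ndarray  # shape (m, 4): columns x1, x2, x3, C
    controls: np.ndarray
    source: str = "integrator"

    def __post_init__(self) -> None:
        if len(self.times) == 0:
            raise ValueError("trajectory must be nonempty")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    @property
    def x1(self) -> np.ndarray:
        return self.states[:, 0]

    @property
    def x2(self) -> np.ndarray:
        return self.states[:, 1]

    @property
    def x3(self) -> np.ndarray:
        return self.states[:, 2]

    @property
    def C(self) -> np.ndarray:
        return self.states[:, 3]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t": self.times, "x1": self.x1, "x2": self.x2,
                             "x3": self.x3, "C": self.C, "mu": self.controls})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


CASE_TABLE = {
    "1": ("none", "none"),
    "2": ("none", "none"),
    "3a": ("constant", "none"),
    "3b": ("continuous", "none"),
    "4a": ("constant", "smc"),
    "4b": ("continuous", "smc"),
    "5a": ("constant", "sc"),
    "5b": ("continuous", "sc"),
    "6a": ("constant", "both"),
    "6b": ("continuous", "both"),
    "6c": ("constant", "both"),
    "6d": ("continuous", "both"),
}


@dataclass(frozen=True)
class CaseSpec:
    """One scenario: case id, dose mode, controller kind, horizon/step."""

    case_id: str
    horizon: float = 100.0
    step: float = 1e-3
    record_every: int = 1

    def __post_init__(self) -> None:
        if self.case_id not in CASE_TABLE:
            raise ValueError(f"unknown case id {self.case_id!r}; "
                             f"valid: {sorted(CASE_TABLE)}")
        if self.horizon <= 0 or self.step <= 0:
            raise ValueError("horizon and step must be > 0")

    @property
    def dose_mode(self) -> str:
        return CASE_TABLE[self.case_id][0]

    @property
    def controller_kind(self) -> str:
        return CASE_TABLE[self.case_id][1]

    def dose_schedule(self) -> DoseSchedule:
        if self.dose_mode == "none":
            return DoseSchedule.none()
        if self.dose_mode == "constant":
            return DoseSchedule.constant()
        return DoseSchedule.continuous()


def integrate(
    params: ModelParams,
    dose: DoseSchedule,
    controller: SMCConfig | SCConfig | None,
    horizon: float = 100.0,
    step: float = 1e-3,
    start: SystemState | None = None,
    freeze_x3: bool = False,
    record_every: int = 1,
) -> Trajectory:
    """Fixed-step RK4 integration of the closed loop over [0, horizon].

    ``controller`` selects the drug law by type (None = open loop);
    ``freeze_x3`` pins the immune population at its initial value (used
    by case 1, which excludes the immune system entirely).  States are
    clamped at zero after every step; any state exceeding 1e6 in
    magnitude aborts with a diagnostic.
    """
    p = params
    st0 = start or initial_state()

    if isinstance(controller, SMCConfig):
        def mu_of(t, x1, x2, x3, C):
            return smc_control(SystemState(t, x1, x2, x3, C), p, controller)
    elif isinstance(controller, SCConfig):
        def mu_of(t, x1, x2, x3, C):
            return sc_control(SystemState(t, x1, x2, x3, C), p, controller)
    elif controller is None:
        def mu_of(t, x1, x2, x3, C):
            return 0.0
    else:
        raise TypeError(f"unsupported controller {controller!r}")

    a1, a2, d1, d2 = p.a1, p.a2, p.d1, p.d2
    e1, e2, e3, e4 = p.e1, p.e2, p.e3, p.e4
    r1, r2, r3, f1, f2 = p.r1, p.r2, p.r3, p.f1, p.f2
    alpha, pr, s = p.alpha, p.p, p.s

    def deriv(t, y):
        x1, x2, x3, C = y
        mu = mu_of(t, x1, x2, x3, C)
        dx1 = a2 * x1 * (1.0 - d2 * x1) - e4 * x2 * x1 - r3 * C
        dx2 = a1 * x2 * (1.0 - d1 * x2) - e2 * x2 * x3 - e3 * x2 * x1 - r2 * C + mu
        dx3 = 0.0 if freeze_x3 else (alpha + pr * x3 * x2 / (s + x2)
                                     - e1 * x3 * x2 - f1 * x3 - r1 * C)
        dC = dose_rate(dose, t) - f2 * C
        return (dx1, dx2, dx3, dC), mu

    n_steps = int(round(horizon / step))
    y = (st0.x1, st0.x2, st0.x3, st0.C)
    times = [st0.t]
    states = [y]
    (_, mu0) = deriv(st0.t, y)
    controls = [mu0]

    h = step
    t = st0.t
    for k in range(n_steps):
        k1, mu = deriv(t, y)
        y2 = tuple(y[j] + 0.5 * h * k1[j] for j in range(4))
        k2, _ = deriv(t + 0.5 * h, y2)
        y3 = tuple(y[j] + 0.5 * h * k2[j] for j in range(4))
        k3, _ = deriv(t + 0.5 * h, y3)
        y4 = tuple(y[j] + h * k3[j] for j in range(4))
        k4, _ = deriv(t + h, y4)
        y = tuple(
            y[j] + h / 6.0 * (k1[j] + 2.0 * k2[j] + 2.0 * k3[j] + k4[j])
            for j in range(4)
        )
        y = tuple(v if v > 0.0 else 0.0 for v in y)  # nonnegativity clamp
        t = st0.t + (k + 1) * h
        if any(abs(v) > BLOWUP_LIMIT for v in y):
            raise RuntimeError(
                f"integration blow-up at t={t:.4f}: state={y}; reduce the step "
                f"or check controller gains")
        if (k + 1) % record_every == 0 or k == n_steps - 1:
            times.append(t)
            states.append(y)
            controls.append(mu)

    return Trajectory(times=np.asarray(times), states=np.asarray(states),
                      controls=np.asarray(controls), source="integrator")


def trajectory_from_approximant(a, horizon: float, case_id: int = 3,
                                ctrl=None, params: ModelParams | None = None,
                                dose: DoseSchedule | None = None,
                                num: int = 201) -> Trajectory:
    """Dense evaluation of a Bernstein candidate as a Trajectory.

    For case 5 the cancer channel is the analytic synergetic decay; the
    immune channel of case 1 is identically zero.  Drug concentration
    comes from the dose closed form for cases with chemotherapy.
    """
    from .bernstein import approx_value
    from .controllers import sc_closed_form_x2

    params = params or ModelParams()
    ss = np.linspace(0.0, a.tau, num)
    times = horizon * ss / a.tau
    x1 = np.array([approx_value(a, "x1", s) for s in ss])
    if case_id == 5:
        x2 = np.array([sc_closed_form_x2(t, x2_0=a.g[0], tau_a=ctrl.tau_a)
                       for t in times])
    else:
        x2 = np.array([approx_value(a, "x2", s) for s in ss])
    if case_id == 1:
        x3 = np.zeros_like(x1)
    else:
        x3 = np.array([approx_value(a, "x3", s) for s in ss])
    if case_id >= 3 and dose is not None:
        C = np.array([concentration_closed_form(dose, params, t) for t in times])
    else:
        C = np.zeros_like(times)
    states = np.column_stack([x1, x2, x3, C])
    return Trajectory(times=times, states=states,
                      controls=np.zeros_like(times), source="ga_bsp")


# --- outcome metrics --------------------------------------------------------

def elimination_time(traj: Trajectory, threshold: float = DEFAULT_THRESHOLD) -> float:
    """First sample time at which x2 falls below ``threshold`` and stays
    below for the rest of the trajectory; ``math.inf`` if never."""
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    below = traj.x2 < threshold
    if below.all():
        return float(traj.times[0])
    last_above = int(np.nonzero(~below)[0][-1])
    if last_above == len(below) - 1:
        return NOT_ELIMINATED
    return float(traj.times[last_above + 1])


def sc_analytic_elimination_time(tau_a: float, x2_0: float = 0.25,
                                 threshold: float = DEFAULT_THRESHOLD) -> float:
    """Inversion of the synergetic closed form: t = tau_a ln(x2(0)/eps)."""
    if threshold <= 0 or x2_0 <= 0:
        raise ValueError("threshold and x2_0 must be > 0")
    if threshold >= x2_0:
        return 0.0
    return tau_a * math.log(x2_0 / threshold)


def min_level(traj: Trajectory, species: str) -> float:
    """Minimum over the trajectory of one species ('x1', 'x2', 'x3', 'C')."""
    col = {"x1": 0, "x2": 1, "x3": 2, "C": 3}
    if species not in col:
        raise ValueError(f"unknown species {species!r}")
    return float(traj.states[:, col[species]].min())


def mean_concentration(traj: Trajectory) -> float:
    """Time-average of the drug concentration (trapezoid rule)."""
    span = traj.times[-1] - traj.times[0]
    return float(np.trapezoid(traj.C, traj.times) / span)


# --- case runner ------------------------------------------------------------

@dataclass
class CaseReport:
    spec: CaseSpec
    trajectories: dict[str, Trajectory]
    metrics: dict[str, float]
    threshold: float = DEFAULT_THRESHOLD

    def to_dict(self) -> dict:
        return {"case": self.spec.case_id, "horizon": self.spec.horizon,
                "step": self.spec.step, "threshold": self.threshold,
                "metrics": self.metrics}


def _controller_for(kind: str, smc_cfg: SMCConfig | None, sc_cfg: SCConfig | None):
    if kind == "smc":
        return smc_cfg or SMCConfig()
    if kind == "sc":
        return sc_cfg or SCConfig()
    return None


def run_case(
    spec: CaseSpec,
    params: ModelParams | None = None,
    smc_cfg: SMCConfig | None = None,
    sc_cfg: SCConfig | None = None,
    threshold: float = DEFAULT_THRESHOLD,
) -> CaseReport:
    """Integrate one treatment case and compute its outcome metrics.

    Comparison cases (6a-6d) run both controllers on the same dose and
    report both elimination times; all other cases emit one trajectory.
    """
    params = params or ModelParams()
    dose = spec.dose_schedule()
    kind = spec.controller_kind
    if kind == "both":
        return compare_controllers(spec, params, smc_cfg=smc_cfg, sc_cfg=sc_cfg,
                                   threshold=threshold)

    freeze = spec.case_id == "1"
    start = initial_state()
    if freeze:
        start = SystemState(t=0.0, x1=start.x1, x2=start.x2, x3=0.0, C=0.0)
    traj = integrate(params, dose, _controller_for(kind, smc_cfg, sc_cfg),
                     horizon=spec.horizon, step=spec.step, start=start,
                     freeze_x3=freeze, record_every=spec.record_every)
    metrics = {
        "elimination_time_days": elimination_time(traj, threshold),
        "min_x1": min_level(traj, "x1"),
        "min_x3": min_level(traj, "x3"),
        "mean_concentration": mean_concentration(traj),
        "final_x2": float(traj.x2[-1]),
    }
    return CaseReport(spec=spec, trajectories={kind: traj}, metrics=metrics,
                      threshold=threshold)


def compare_controllers(
    spec: CaseSpec,
    params: ModelParams | None = None,
    smc_cfg: SMCConfig | None = None,
    sc_cfg: SCConfig | None = None,
    threshold: float = DEFAULT_THRESHOLD,
) -> CaseReport:
    """Run SMC and SC on the same dose schedule and report both."""
    params = params or ModelParams()
    if spec.controller_kind != "both":
        raise ValueError(f"case {spec.case_id} is not a comparison case")
    dose = spec.dose_schedule()
    trajs = {}
    metrics = {}
    for kind in ("smc", "sc"):
        traj = integrate(params, dose, _controller_for(kind, smc_cfg, sc_cfg),
                         horizon=spec.horizon, step=spec.step,
                         record_every=spec.record_every)
        trajs[kind] = traj
        metrics[f"elimination_time_{kind}"] = elimination_time(traj, threshold)
        metrics[f"min_x1_{kind}"] = min_level(traj, "x1")
    metrics["sc_faster"] = float(
        metrics["elimination_time_sc"] < metrics["elimination_time_smc"])
    return CaseReport(spec=spec, trajectories=trajs, metrics=metrics,
                      threshold=threshold)


def sweep_tau(
    values: Iterable[float],
    params: ModelParams | None = None,
    dose: DoseSchedule | None = None,
    horizon: float = 100.0,
    step: float = 1e-3,
    threshold: float = DEFAULT_THRESHOLD,
) -> pd.DataFrame:
    """Synergetic convergence-time sweep: analytic and simulated
    elimination times for each tau_a."""
    params = params or ModelParams()
    dose = dose or DoseSchedule.constant()
    rows = []
    for tau_a in values:
        cfg = SCConfig(tau_a=tau_a)
        traj = integrate(params, dose, cfg, horizon=horizon, step=step)
        rows.append({
            "tau_a": tau_a,
            "analytic_days": sc_analytic_elimination_time(tau_a, threshold=threshold),
            "simulated_days": elimination_time(traj, threshold),
        })
    return pd.DataFrame(rows)
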