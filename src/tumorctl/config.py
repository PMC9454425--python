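"""Validated run configuration (YAML/JSON) with documented defaults.

Every default that substitutes for an externally unspecified constant
(model rates, dose amplitudes, GA hyperparameters) lives in the schema
below and is logged at startup, so a run record always shows the fully
resolved configuration.  Unknown keys are rejected with field paths.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import model as _model
from .controllers import SCConfig, SMCConfig
from .ga import GAConfig
from .model import DoseSchedule, ModelParams

log = logging.getLogger("tumorctl")


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ModelSection(_Strict):
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

    def build(self) -> ModelParams:
        return ModelParams(**self.model_dump())


class DoseSection(_Strict):
    mode: str = "constant"
    v: float | None = None
    lam: float | None = None

    @model_validator(mode="after")
    def _check(self):
        if self.mode not in ("none", "constant", "continuous_exponential"):
            raise ValueError(f"dose.mode must be none/constant/continuous_exponential,"
                             f" got {self.mode!r}")
        return self

    def build(self) -> DoseSchedule:
        if self.mode == "none":
            return DoseSchedule.none()
        if self.mode == "constant":
            return DoseSchedule.constant(self.v if self.v is not None
                                         else _model.DEFAULT_CONSTANT_V)
        return DoseSchedule.continuous(
            self.v if self.v is not None else _model.DEFAULT_CONTINUOUS_V,
            self.lam if self.lam is not None else _model.DEFAULT_CONTINUOUS_LAMBDA)


class SMCSection(_Strict):
    partial: float = Field(1.0, ge=0.0, le=1.0)
    m1: float = Field(1.0, gt=0.0)
    eta: float = Field(0.0, ge=0.0)
    smoothing_width: float = Field(1e-3, ge=0.0)

    def build(self) -> SMCConfig:
        return SMCConfig(**self.model_dump())


class SCSection(_Strict):
    m2: float = Field(1.0, gt=0.0)
    tau_a: float = Field(0.01, gt=0.0)

    def build(self) -> SCConfig:
        return SCConfig(**self.model_dump())


class GASection(_Strict):
    population_size: int = 100
    generations: int = 500
    crossover_rate: float = 0.9
    mutation_rate: float = 0.1
    mutation_scale: float = 0.1
    mutation_decay: float = 0.995
    coefficient_bounds: tuple[float, float] = (-2.0, 2.0)
    elitism_count: int = 1
    seed: int = 42

    def build(self) -> GAConfig:
        return GAConfig(**self.model_dump())


class SimulationSection(_Strict):
    case: str = "5a"
    horizon: float = Field(100.0, gt=0.0)
    step: float = Field(1e-3, gt=0.0)
    threshold: float = Field(1e-3, gt=0.0)
    order: int = Field(10, ge=1)


class RunConfig(_Strict):
    model: ModelSection = ModelSection()
    dose: DoseSection = DoseSection()
    smc: SMCSection = SMCSection()
    sc: SCSection = SCSection()
    ga: GASection = GASection()
    simulation: SimulationSection = SimulationSection()
    seed: int = 42


def load_config(path: str | Path | None) -> RunConfig:
    """Load and validate a YAML/JSON run configuration.

    ``None`` or an empty file yields the all-defaults configuration.
    Unknown keys and out-of-range values raise with the offending field
    path.  The fully resolved configuration is logged.
    """
    if path is None:
        cfg = RunConfig()
    else:
        text = Path(path).read_text()
        data = yaml.safe_load(text) if text.strip() else {}
        cfg = RunConfig.model_validate(data or {})
    log.info("resolved configuration: %s", json.dumps(cfg.model_dump(), default=list))
    return cfg


def save_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.model_dump(), sort_keys=False))
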