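"""Run configuration: YAML-backed, schema-validated via pydantic.

A config names the model (the bundled toy, or a CellML file), the decision
conductances with bounds, the marker bands, trust-region settings and the
protocol profile.  Marker-band defaults are the selected experimental ranges
used for human ventricular calibration (APD90 280-310 ms, triangulation
44-112 ms, systolic [Ca]i 0.602-2.01 uM at 1 Hz and 0.523-1.68 uM at 0.5 Hz,
diastolic 0.097-0.33 / 0.091-0.32 uM, tau_slow 70-110 s); ``bands: auto``
instead derives bands from the configured model's own baseline (+/-10%,
+/-15% for calcium), which is the sensible choice for the toy model.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

from .biomarkers import MARKER_NAMES
from .design import ConstraintSpec, DecisionSpace, TrustRegionParams, DEFAULT_BOUND

__all__ = ["RunConfig", "load_config", "SELECTED_RANGES", "build_problem"]

# selected experimental ranges for human ventricular epicardial calibration
SELECTED_RANGES = {
    "APD90": (280.0, 310.0),          # ms
    "triangulation": (44.0, 112.0),   # ms
    "Ca_sys_1Hz": (0.602, 2.01),      # uM
    "Ca_sys_0.5Hz": (0.523, 1.68),    # uM
    "Ca_dia_1Hz": (0.097, 0.33),      # uM
    "Ca_dia_0.5Hz": (0.091, 0.32),    # uM
    "tau_slow": (70.0, 110.0),        # s
}


class DecisionVariable(BaseModel):
    name: str
    G0: float | None = None   # default: taken from the model
    xL: float = -DEFAULT_BOUND
    xU: float = DEFAULT_BOUND

    @model_validator(mode="after")
    def _check_bounds(self):
        if not self.xL < self.xU:
            raise ValueError(f"decision variable {self.name}: need xL < xU")
        return self


class TrustRegionConfig(BaseModel):
    delta0: float = 2.0
    delta_max: float = 6.0
    rho_L: float = 0.25
    delta1: float = 1e-3
    delta2: float = 1e-3
    delta3: float = 1e-3
    max_iterations: int = 20
    levels: int = 3
    marker_guard_frac: float = 0.1

    def to_params(self) -> TrustRegionParams:
        return TrustRegionParams(**self.model_dump())


class StimulusConfig(BaseModel):
    amplitude: float | None = None  # pA/pF; default: the model's own
    duration: float | None = None   # ms


class RunConfig(BaseModel):
    """Top-level run configuration (YAML)."""

    model: str = "toy"
    decision_variables: list[DecisionVariable] = Field(
        default_factory=lambda: [DecisionVariable(name=n) for n in
                                 ("G_Ca", "G_K", "G_K1", "G_NaK")])
    bands: dict[str, tuple[float, float]] | str = "auto"
    trust_region: TrustRegionConfig = Field(default_factory=TrustRegionConfig)
    profile: str = "test"
    stimulus: StimulusConfig = Field(default_factory=StimulusConfig)
    workers: int = 1
    seed: int = 0
    output_dir: str = "results"

    @field_validator("profile")
    @classmethod
    def _check_profile(cls, v):
        if v not in ("test", "paper"):
            raise ValueError("profile must be 'test' or 'paper'")
        return v

    @field_validator("bands")
    @classmethod
    def _check_bands(cls, v):
        if isinstance(v, str):
            if v != "auto":
                raise ValueError("bands must be 'auto' or a mapping")
            return v
        unknown = set(v) - set(MARKER_NAMES)
        if unknown:
            raise ValueError(f"unknown marker band(s): {sorted(unknown)}; "
                             f"valid: {list(MARKER_NAMES)}")
        for name, (lo, hi) in v.items():
            if not lo < hi:
                raise ValueError(f"band {name}: need lower < upper")
        return v

    @field_validator("model")
    @classmethod
    def _check_model(cls, v):
        if v != "toy" and not v.startswith("cellml:"):
            raise ValueError("model must be 'toy' or 'cellml:<path>'")
        return v

    # -- materialization ---------------------------------------------------

    def build_model(self):
        if self.model == "toy":
            from .models import ToyVentricularModel
            m = ToyVentricularModel()
        else:
            from .cellml import load_cellml_model, TOY_CURRENT_MAP
            m = load_cellml_model(self.model.split(":", 1)[1],
                                  current_map=TOY_CURRENT_MAP)
        if self.stimulus.amplitude is not None:
            m.stim_amplitude = self.stimulus.amplitude
        if self.stimulus.duration is not None:
            m.stim_duration = self.stimulus.duration
        return m

    def resolve_bands(self, model=None) -> ConstraintSpec:
        if self.bands == "auto":
            from .evaluator import PROFILES, measure_markers
            model = model if model is not None else self.build_model()
            base = measure_markers(model, **PROFILES[self.profile])
            mvec = base.as_array()
            frac = np.array([0.10, 0.10, 0.15, 0.15, 0.15, 0.15, 0.10])
            half = frac * np.abs(mvec)
            return ConstraintSpec(MARKER_NAMES, mvec - half, mvec + half)
        full = dict(SELECTED_RANGES)
        full.update(self.bands)
        return ConstraintSpec(MARKER_NAMES,
                              [full[n][0] for n in MARKER_NAMES],
                              [full[n][1] for n in MARKER_NAMES])

    def to_yaml(self) -> str:
        return yaml.safe_dump(json.loads(self.model_dump_json()),
                              sort_keys=False)

    def digest(self) -> str:
        return hashlib.sha256(self.model_dump_json().encode()).hexdigest()[:12]


def load_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig(**data)


def build_problem(config: RunConfig, model=None):
    """Materialize (model, OptimizationProblem, evaluator) from a config."""
    from .evaluator import make_model_evaluator
    from .optimizer import OptimizationProblem

    model = model if model is not None else config.build_model()
    names = [d.name for d in config.decision_variables]
    G0 = [d.G0 if d.G0 is not None else model.params[d.name]
          for d in config.decision_variables]
    space = DecisionSpace(
        names, G0,
        xL=[d.xL for d in config.decision_variables],
        xU=[d.xU for d in config.decision_variables])
    constraints = config.resolve_bands(model)
    problem = OptimizationProblem(space=space, constraints=constraints,
                                  trust_region=config.trust_region.to_params())
    evaluator = make_model_evaluator(model, space, constraints,
                                     profile=config.profile,
                                     workers=config.workers)
    return model, problem, evaluator
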