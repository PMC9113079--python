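"""Run configuration: validated, YAML round-trippable, content-hashable.

The defaults are the frozen configuration used for the whole study sweep —
no table- or row-specific tuning is applied anywhere downstream.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, Field, model_validator

from .branching import DEFAULT_MVR_EXPONENT
from .hemodynamics import BoundaryConditions, FluidProperties, LossModelParams

__all__ = ["RunConfig", "FluidConfig", "BoundaryConfig", "LossConfig"]


class FluidConfig(BaseModel):
    viscosity_Pa_s: float = Field(default=0.0035, gt=0)
    density_kg_m3: float = Field(default=1056.0, gt=0)


class BoundaryConfig(BaseModel):
    inlet_pressure_Pa: float = Field(default=13332.2, gt=0)
    venous_pressure_Pa: float = Field(default=0.0, ge=0)
    outlet_mvr_Pa_s_m3: float = Field(default=8.721e9, gt=0)
    mvr_delta_Pa_s_m3: float = Field(default=2e9, ge=0)

    @model_validator(mode="after")
    def _check(self) -> "BoundaryConfig":
        if self.inlet_pressure_Pa <= self.venous_pressure_Pa:
            raise ValueError("inlet pressure must exceed venous pressure")
        if self.outlet_mvr_Pa_s_m3 - self.mvr_delta_Pa_s_m3 <= 0:
            raise ValueError("mvr_delta must leave the low MVR positive")
        return self


class LossConfig(BaseModel):
    kt: float = Field(default=1.0, ge=0)
    cc_rounded: float = Field(default=1.0, gt=0, le=1)
    cc_uniform: float = Field(default=0.70, gt=0, le=1)
    cc_rectangular: float = Field(default=0.68, gt=0, le=1)

    @model_validator(mode="after")
    def _ordered(self) -> "LossConfig":
        if not (self.cc_rectangular <= self.cc_uniform <= self.cc_rounded):
            raise ValueError("require cc_rectangular <= cc_uniform <= cc_rounded")
        return self


class RunConfig(BaseModel):
    """Everything needed to reproduce a sweep deterministically."""

    fluid: FluidConfig = Field(default_factory=FluidConfig)
    boundary: BoundaryConfig = Field(default_factory=BoundaryConfig)
    loss: LossConfig = Field(default_factory=LossConfig)
    grid_step_mm: float = Field(default=0.1, gt=0)
    mvr_exponent: float = Field(default=DEFAULT_MVR_EXPONENT, gt=0)
    significance_threshold: float = Field(default=0.80, gt=0, lt=1)
    output_dir: str = "results"
    verbosity: int = Field(default=1, ge=0, le=3)

    # --- domain-object factories -------------------------------------
    def make_fluid(self) -> FluidProperties:
        return FluidProperties(**self.fluid.model_dump())

    def make_bc(self, mvr: float | None = None) -> BoundaryConditions:
        return BoundaryConditions(
            inlet_pressure_Pa=self.boundary.inlet_pressure_Pa,
            venous_pressure_Pa=self.boundary.venous_pressure_Pa,
            outlet_mvr_Pa_s_m3=(
                mvr if mvr is not None else self.boundary.outlet_mvr_Pa_s_m3
            ),
        )

    def make_loss(self) -> LossModelParams:
        return LossModelParams(**self.loss.model_dump())

    # --- serialization ------------------------------------------------
    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(self.model_dump(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.model_validate(data)

    def content_hash(self) -> str:
        """Stable hash of the full configuration (12 hex chars)."""
        blob = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
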