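"""Analysis configuration: validated before any computation starts.

Unknown keys are rejected so that a typo in a YAML file fails loudly
instead of silently falling back to a default.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, ValidationError, model_validator

from .errors import ConfigError

__all__ = ["AnalysisConfig", "load_config"]


class AnalysisConfig(BaseModel):
    """Everything needed to run a batch CAT analysis."""

    model_config = ConfigDict(extra="forbid")

    inputs: list[str]
    mode: Literal["tension", "bending"] = "tension"
    pixel_scale: float | None = None  # m/px; overrides the sidecar value
    surface_tension: float = 0.07275  # N/m
    density: float = 998.0  # kg/m^3
    gravity: float = 9.81  # m/s^2
    threshold: float | Literal["auto"] = "auto"
    stencil: Literal[2, 3] = 3
    residuals: Literal["vertical", "orthogonal"] = "orthogonal"
    mc_n: int = 200
    seed: int = 0
    angle_form: Literal["sin", "tan"] = "sin"
    specimen_length: float | None = None  # m (bending mode)
    specimen_diameter: float | None = None  # m (bending mode)
    specimen_tilt: float = 0.0  # rad
    angle_window_px: int = 100  # columns used for the fiber-angle line fit
    manual_points: str | None = None  # CSV with clicked coordinates
    out_csv: str | None = None
    out_json: str | None = None

    @model_validator(mode="after")
    def _check(self):
        if not self.inputs:
            raise ValueError("at least one input sequence is required")
        if self.mode == "bending" and (
            self.specimen_length is None or self.specimen_diameter is None
        ):
            raise ValueError(
                "bending mode requires specimen_length and specimen_diameter"
            )
        if self.surface_tension <= 0 or self.density <= 0 or self.gravity <= 0:
            raise ValueError("fluid properties must be positive")
        if self.pixel_scale is not None and self.pixel_scale <= 0:
            raise ValueError("pixel_scale must be positive")
        return self


def load_config(path=None, **overrides) -> AnalysisConfig:
    """Build an AnalysisConfig from an optional YAML file plus overrides."""
    data: dict = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text())
        if not isinstance(loaded, dict):
            raise ConfigError(f"config file {path} must contain a mapping")
        data.update(loaded)
    data.update({k: v for k, v in overrides.items() if v is not None})
    try:
        return AnalysisConfig(**data)
    except ValidationError as exc:
        raise ConfigError(str(exc)) from exc
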