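"""Program configuration.

Every knob the method leaves open — band width, flag thresholds, trigger
window, episode length, tip cadence, toolbox catalogue — lives here in one
validated structure, loadable from YAML, so defaults are visible in a single
place and overridable per program.
"""

from __future__ import annotations

import hashlib
import json

import yaml
from pydantic import BaseModel, Field, ValidationError, field_validator

from .adherence import BandSpec
from .energy_model import ModelParams
from .intervention import DEFAULT_CATALOGUE, TipPhase, ToolboxStrategy

__all__ = ["ProgramConfig", "ConfigError", "load_config"]


class ConfigError(ValueError):
    pass


class BandConfig(BaseModel):
    mode: str = "percent_baseline"
    pct: float = 2.0
    upper_kg: float | None = None
    lower_kg: float | None = None

    def to_band_spec(self) -> BandSpec:
        try:
            return BandSpec(mode=self.mode, pct=self.pct,
                            upper_kg=self.upper_kg, lower_kg=self.lower_kg)
        except ValueError as exc:
            raise ConfigError(str(exc)) from exc


class TriggerConfig(BaseModel):
    k: int = 3
    n: int = 5
    include_red_green: bool = False
    no_data_counts_in_n: bool = True

    @field_validator("n")
    @classmethod
    def _ordered(cls, v, info):
        if "k" in info.data and v < info.data["k"]:
            raise ValueError("need n >= k")
        return v


class FlagConfig(BaseModel):
    slope_window: int = 7
    min_slope_points: int = 3
    plateau_z: float = 1.645
    upper_edge_fraction: float = Field(default=0.2, ge=0.0, le=1.0)


class TipPhaseConfig(BaseModel):
    length_days: int
    cadence: str


class ProgramConfig(BaseModel):
    """Full program configuration with field-level validation."""

    model_params: dict = Field(default_factory=dict)
    band: BandConfig = Field(default_factory=BandConfig)
    trigger: TriggerConfig = Field(default_factory=TriggerConfig)
    flags: FlagConfig = Field(default_factory=FlagConfig)
    episode_window_days: int = 14
    reminder_after_missing_days: int = 3
    outlier_threshold: float = 0.05
    collapse_first_of_day: bool = True
    tip_phases: list[TipPhaseConfig] = Field(default_factory=lambda: [
        TipPhaseConfig(length_days=56, cadence="weekly"),
        TipPhaseConfig(length_days=56, cadence="biweekly"),
        TipPhaseConfig(length_days=56, cadence="monthly"),
    ])
    toolbox: list[dict] = Field(default_factory=lambda: [
        {"id": s.id, "label": s.label, "intensity_rank": s.intensity_rank,
         "cost_tier": s.cost_tier} for s in DEFAULT_CATALOGUE])
    units: str = "us"     # "us" | "si" display preference

    def params(self) -> ModelParams:
        try:
            return ModelParams.from_dict({**ModelParams().to_dict(), **self.model_params})
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"bad model params: {exc}") from exc

    def band_spec(self) -> BandSpec:
        return self.band.to_band_spec()

    def catalogue(self) -> list[ToolboxStrategy]:
        return [ToolboxStrategy(**item) for item in self.toolbox]

    def phases(self) -> list[TipPhase]:
        return [TipPhase(p.length_days, p.cadence) for p in self.tip_phases]

    def digest(self) -> str:
        """Stable hash of the effective configuration, for run logs."""
        blob = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def load_config(path=None) -> ProgramConfig:
    """Load a YAML config (missing keys take defaults); None -> all defaults."""
    if path is None:
        return ProgramConfig()
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    try:
        cfg = ProgramConfig(**raw)
    except ValidationError as exc:
        raise ConfigError(str(exc)) from exc
    # eagerly materialize every derived object so bad values fail at load time
    cfg.params()
    cfg.band_spec()
    try:
        cfg.catalogue()
        cfg.phases()
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc
    return cfg
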