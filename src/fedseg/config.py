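"""Validated run configuration for desk-scale federations.

A run is described by one YAML or JSON document: the site profiles of
the synthetic cohort, the iteration budget, the model hyperparameters,
and the federation policies (weighting, threshold, determinism, seeds).
Unknown keys are rejected by name; defaults are filled in so a minimal
config needs only ``sites`` and ``n_iterations``.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .errors import ConfigurationError
from .phantoms import SiteProfile
from .unet import ModelConfig


class SiteSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")

    site_id: str
    n_patients: int = Field(ge=2)
    seed: int = Field(ge=0)
    intensity_offset: float = 0.0
    noise_sd: float = Field(default=5.0, ge=0.0)
    tumor_radius_range: tuple[float, float] = (4.0, 9.0)
    lung_ellipse_params: tuple[float, float] = (24.0, 18.0)

    def to_profile(self) -> SiteProfile:
        return SiteProfile(
            site_id=self.site_id,
            n_patients=self.n_patients,
            seed=self.seed,
            intensity_offset=self.intensity_offset,
            noise_sd=self.noise_sd,
            tumor_radius_range=self.tumor_radius_range,
            lung_ellipse_params=self.lung_ellipse_params,
        )


class ModelSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")

    depth: int = Field(default=2, ge=1)
    base_filters: int = Field(default=8, ge=1)
    input_shape: tuple[int, int] = (64, 64)
    learning_rate: float = Field(default=3e-3, gt=0)
    batch_size: int = Field(default=4, ge=1)
    loss_name: Literal["dice_loss", "bce_dice"] = "bce_dice"

    def to_model_config(self) -> ModelConfig:
        return ModelConfig(
            depth=self.depth,
            base_filters=self.base_filters,
            input_shape=self.input_shape,
            learning_rate=self.learning_rate,
            batch_size=self.batch_size,
            loss_name=self.loss_name,
        )


class FederationConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    sites: list[SiteSettings] = Field(min_length=1)
    n_iterations: int = Field(ge=1)
    steps_per_iteration: int = Field(default=50, ge=1)
    split_fraction: float = Field(default=0.8, gt=0.0, lt=1.0)
    weighting: Literal["sample_weighted", "uniform"] = "sample_weighted"
    threshold: float = Field(default=0.5, gt=0.0, lt=1.0)
    deterministic: bool = True
    seed: int = Field(default=0, ge=0)
    model: ModelSettings = Field(default_factory=ModelSettings)
    token_lifetime_s: float = Field(default=600.0, gt=0.0)
    task_id: str = "task-0"

    def site_profiles(self) -> list[SiteProfile]:
        ids = [s.site_id for s in self.sites]
        if len(set(ids)) != len(ids):
            raise ConfigurationError("duplicate site_id in configuration")
        return [s.to_profile() for s in self.sites]

    def model_cfg(self) -> ModelConfig:
        return self.model.to_model_config()


def _format_validation_error(exc: ValidationError) -> str:
    lines = []
    for err in exc.errors():
        loc = ".".join(str(p) for p in err["loc"]) or "<root>"
        lines.append(f"{loc}: {err['msg']}")
    return "; ".join(lines)


def parse_config(data: dict) -> FederationConfig:
    try:
        return FederationConfig.model_validate(data)
    except ValidationError as exc:
        raise ConfigurationError(
            f"invalid configuration: {_format_validation_error(exc)}"
        ) from exc


def load_config(path) -> FederationConfig:
    """Load and validate a YAML/JSON run configuration file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ConfigurationError(f"{path}: configuration must be a mapping")
    return parse_config(data)
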