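"""Run configuration: validated, YAML-round-trippable, strict about keys.

Defaults follow the reference analysis protocol: 10-mm smoothing, global-mean
target 1.0, voxel p < 0.001 with 25-voxel extent, UPDRS-III and LEDD as
partial-correlation covariates at alpha 0.05, Adam at lr 3e-3 / weight decay
2e-3, and 10-fold cross-validation.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .nn import TrainConfig
from .synthetic import CohortConfig, default_cohort_config

__all__ = [
    "PreprocessConfig", "StatsConfig", "CorrConfig", "EvalConfig", "RunConfig",
    "load_config", "save_config", "ConfigError",
]


class ConfigError(ValueError):
    """Configuration failed validation; the message names the offending key."""


class PreprocessConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    fwhm_mm: float = Field(default=10.0, ge=0)
    target: float = Field(default=1.0, gt=0)


class StatsConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    p_voxel: float = Field(default=0.001, gt=0, lt=1)
    extent_k: int = Field(default=25, ge=1)
    connectivity: int = 26

    def model_post_init(self, __context) -> None:
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18 or 26")


class CorrConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    covariates: list[str] = Field(default_factory=lambda: ["updrs3", "ledd"])
    alpha: float = Field(default=0.05, gt=0, lt=1)


class EvalConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    tasks: list[str] = Field(default_factory=lambda: ["fog_vs_nfog"])
    models: list[str] = Field(default_factory=lambda: ["cnn3d"])
    k: int = Field(default=10, ge=2)


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    cohort: CohortConfig = Field(default_factory=default_cohort_config)
    preprocess: PreprocessConfig = Field(default_factory=PreprocessConfig)
    stats: StatsConfig = Field(default_factory=StatsConfig)
    corr: CorrConfig = Field(default_factory=CorrConfig)
    train: TrainConfig = Field(default_factory=TrainConfig)
    evaluation: EvalConfig = Field(default_factory=EvalConfig)
    output_dir: str = "fogpet_run"
    seed: int = 0


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration.

    Unset fields take the protocol defaults; unknown keys and invalid values
    raise :class:`ConfigError` naming the offending key path.
    """
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text()) or {}
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: not parseable YAML ({exc})") from exc
    try:
        return RunConfig(**raw)
    except ValidationError as exc:
        locs = "; ".join(
            ".".join(str(p) for p in err["loc"]) + f": {err['msg']}" for err in exc.errors()
        )
        raise ConfigError(f"{path}: invalid configuration ({locs})") from exc


def save_config(config: RunConfig, path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(config.model_dump(mode="json"), sort_keys=False))
    return path
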