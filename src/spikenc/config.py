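"""Structured run configuration.

A single YAML file can drive every pipeline stage; unknown keys are
rejected so typos fail fast.  CLI flags override config values.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, ValidationError

from .errors import ConfigurationError

__all__ = [
    "FrontendConfig",
    "STDPSettings",
    "RegressionConfig",
    "DecodingConfig",
    "RunConfig",
    "load_config",
    "config_hash",
]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class FrontendConfig(_Strict):
    preset: str = "character_natural"
    T: int = 30
    threshold: float = 50.0


class STDPSettings(_Strict):
    a_plus: float = 0.004
    a_minus: float = -0.003
    convergence_stop: float = 0.01
    winners_per_image: int = 1
    inhibition_radius: int = 2
    max_epochs: int = 64
    rate_boost_every: int | None = 500
    a_plus_cap: float = 0.15


class RegressionConfig(_Strict):
    folds: int = 3
    seed: int = 0
    intercept: bool = True


class DecodingConfig(_Strict):
    recon_voxels: int = 200
    ident_voxels: int = 500
    top_n: int = 15
    shrinkage: float = 0.1


class RunConfig(_Strict):
    frontend: FrontendConfig = FrontendConfig()
    stdp: STDPSettings = STDPSettings()
    regression: RegressionConfig = RegressionConfig()
    decoding: DecodingConfig = DecodingConfig()


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration; unknown keys are errors."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as exc:
        raise ConfigurationError(f"invalid config {path}: {exc}") from exc


def config_hash(cfg: RunConfig) -> str:
    """Short deterministic hash of a configuration (for run manifests)."""
    blob = json.dumps(cfg.model_dump(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
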