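"""Validated run configuration (YAML-loadable) with provenance hashing."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, Field, field_validator

from .constants import FREQ_DEFAULT


class AsymmetrySpec(BaseModel):
    """One injected left-right offset: applied to ``parameter`` inside ``roi``."""

    model: Literal["noddi", "sandi", "smt"]
    roi: str
    parameter: str
    offset: float


class RunConfig(BaseModel):
    """Everything a pipeline run needs; validated before any stage executes.

    ``beta`` has no default on purpose: it is the one constant of the
    conductivity relation that cannot be measured from diffusion data, so a
    run must state it explicitly (0.41 is the conventional choice).
    """

    beta: float = Field(gt=0)
    models: list[Literal["noddi", "sandi", "smt"]] = ["noddi", "sandi", "smt"]
    frequency: float = Field(default=FREQ_DEFAULT, gt=0)
    bounds: tuple[float, float] = (-0.05, 0.05)
    alpha: float = Field(default=0.05, gt=0, lt=1)
    seed: int = 0
    n_subjects: int = Field(default=30, ge=1)
    grid_shape: tuple[int, int, int] = (64, 64, 64)
    noddi_scaling: Literal["scaled", "canonical"] = "scaled"
    sigma_h_overrides: dict[str, float] = {}
    asymmetry: list[AsymmetrySpec] = []
    comparison_mode: Literal["paired", "pooled"] = "paired"
    write_volumes: bool = False

    @field_validator("bounds")
    @classmethod
    def _bounds_ordered(cls, v):
        if not v[0] < v[1]:
            raise ValueError(f"equivalence bounds must satisfy low < high, got {v}")
        return v

    @field_validator("models")
    @classmethod
    def _models_nonempty(cls, v):
        if not v:
            raise ValueError("at least one model required")
        return v

    def config_hash(self) -> str:
        canon = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(raw)
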