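"""Run configuration: schema-validated weights, bounds, box and solver settings.

A `RunConfig` can be loaded from JSON or YAML; every field has an explicit
default, and `effective()` dumps the fully-defaulted configuration so runs
are reproducible from their logs.
"""
from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, Field, model_validator

from .objective import ConstraintBounds, CostWeights
from .optimize import SearchBox
from .sensitivity import SensitivityConfig
from .wk3 import DEFAULT_STEP_MS


class WeightsConfig(BaseModel):
    gamma: tuple[float, float, float] = (1.0, 1.0, 1.0)
    #: Reference means m_i; None means "use the measured values".
    ref_means: tuple[float, float, float] | None = None

    def build(self, measured=None) -> CostWeights:
        if self.ref_means is not None:
            return CostWeights(gamma=self.gamma, ref_means=self.ref_means)
        if measured is None:
            raise ValueError("ref_means unset and no measured features provided")
        return CostWeights.from_measured(measured, gamma=self.gamma)


class ConstraintsConfig(BaseModel):
    b0: float = 0.5
    b1: float = 6.0
    b2: float = 0.7
    b3: float = 4.0
    kappa: float = Field(default=1e4, gt=0)

    def build(self) -> ConstraintBounds:
        return ConstraintBounds(**self.model_dump())


class BoxConfig(BaseModel):
    lower: tuple[float, float, float] = (1.0, 10.0, 1.0)
    upper: tuple[float, float, float] = (50.0, 300.0, 100.0)

    def build(self) -> SearchBox:
        return SearchBox(lower=self.lower, upper=self.upper)


class SensitivitySettings(BaseModel):
    rel_range: float = Field(default=0.10, gt=0, lt=1)
    n_iv: int = Field(default=100, ge=2)
    n_sobol: int = Field(default=256, ge=8)
    sigma2: float = Field(default=0.2, gt=0)
    n_bootstrap: int = Field(default=200, ge=0)
    refit: str = "warm"

    def build(self, seed: int = 0) -> SensitivityConfig:
        return SensitivityConfig(seed=seed, **self.model_dump())


class RunConfig(BaseModel):
    """Top-level configuration for fitting and sensitivity runs."""

    weights: WeightsConfig = Field(default_factory=WeightsConfig)
    constraints: ConstraintsConfig = Field(default_factory=ConstraintsConfig)
    box: BoxConfig = Field(default_factory=BoxConfig)
    sensitivity: SensitivitySettings = Field(default_factory=SensitivitySettings)
    solver_step: float = Field(default=DEFAULT_STEP_MS, gt=0)
    seed: int = 0
    n_global: int = Field(default=256, ge=1)
    n_refine: int = Field(default=8, ge=1)

    @model_validator(mode="after")
    def _check_box(self) -> "RunConfig":
        self.box.build()  # raises on inconsistent bounds
        return self

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.model_validate(data or {})

    def effective(self) -> dict:
        """Fully-defaulted configuration as a plain dict."""
        return self.model_dump(mode="json")

    def digest(self) -> str:
        """Stable hash of the effective configuration, for provenance."""
        blob = json.dumps(self.effective(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
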