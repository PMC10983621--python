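"""Run configuration: schema-validated before any computation starts."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, Field, field_validator

from .depreciation import DEFAULT_INTEREST_RATE, DEFAULT_LIFESPANS, DepreciationPolicy

__all__ = ["Config", "CascadeOptions", "DepreciationConfig", "load_config"]


class DepreciationConfig(BaseModel):
    interest_rate: float = DEFAULT_INTEREST_RATE
    lifespans: dict[str, int] = Field(default_factory=lambda: dict(DEFAULT_LIFESPANS))

    def policy(self) -> DepreciationPolicy:
        return DepreciationPolicy(dict(self.lifespans), self.interest_rate)


class CascadeOptions(BaseModel):
    order: list[str] | str = "auto"  # explicit center list or "auto"
    uniform_fallback: bool = False


class Config(BaseModel):
    """Everything a run needs; the manifest records its hash for reproducibility."""

    currency: str = "USD"
    exchange_rate: float  # source -> reporting currency; 1.0 = identity
    depreciation: DepreciationConfig = Field(default_factory=DepreciationConfig)
    cascade: CascadeOptions = Field(default_factory=CascadeOptions)
    aggregation_weighted: bool = True  # volume-weighted level aggregates
    target_year: int = 2023
    excluded_years: list[int] = Field(default_factory=lambda: [2020, 2021])
    market_salaries: dict[str, float] = Field(
        default_factory=lambda: {"nurse": 48000.0}
    )
    seed: int = 0

    @field_validator("exchange_rate")
    @classmethod
    def _positive_rate(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("exchange_rate must be > 0")
        return v

    def content_hash(self) -> str:
        blob = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path: str | Path) -> Config:
    """Load a YAML or JSON config file and validate its schema."""
    path = Path(path)
    data = yaml.safe_load(path.read_text())
    return Config.model_validate(data)
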