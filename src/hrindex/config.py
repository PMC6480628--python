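"""Validated run configuration for the command-line pipeline.

A single JSON document configures disease definitions, KDE options, the
curve grid and generator overrides.  Validation is strict: unknown keys are
rejected so that typos fail loudly instead of silently falling back to
defaults.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal, Optional

from pydantic import BaseModel, ConfigDict, Field, ValidationError, field_validator

from .cohort import DiseaseDefinition, RiskFactor, load_disease_config
from .errors import InputError
from .simulate import GeneratorConfig

__all__ = ["RunConfig", "KdeOptions", "GridOptions", "GeneratorOptions", "load_run_config"]


class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid")


class DiseaseRuleSpec(_StrictModel):
    factor: RiskFactor
    threshold: float = Field(gt=0)


class DiseaseSpec(_StrictModel):
    name: str
    rules: list[DiseaseRuleSpec] = Field(min_length=1)


class KdeOptions(_StrictModel):
    """Bandwidth rule and range-handling mode for the fitted densities."""

    bandwidth: Literal["nrd0"] | float = "nrd0"
    extrapolate_low: bool = False
    min_state_samples: int = Field(default=2, ge=2)

    @field_validator("bandwidth")
    @classmethod
    def _positive_bandwidth(cls, v):
        if isinstance(v, float) and not v > 0:
            raise ValueError("fixed bandwidth must be positive")
        return v


class GridOptions(_StrictModel):
    points: int = Field(default=512, ge=2)
    pad: float = Field(default=0.05, ge=0)
    lo: Optional[float] = None
    hi: Optional[float] = None


class GeneratorOptions(_StrictModel):
    n_subjects: int = Field(default=2000, ge=1)
    disease_prevalence: float = Field(default=0.3, ge=0, le=1)
    min_state_count: int = Field(default=10, ge=0)
    max_retries: int = Field(default=25, ge=1)


class RunConfig(_StrictModel):
    """Top-level configuration shared by all CLI verbs."""

    diseases: Optional[list[DiseaseSpec]] = None
    kde: KdeOptions = Field(default_factory=KdeOptions)
    grid: GridOptions = Field(default_factory=GridOptions)
    generator: GeneratorOptions = Field(default_factory=GeneratorOptions)
    seed: Optional[int] = None
    log_level: str = "INFO"

    def disease_definitions(self) -> list[DiseaseDefinition]:
        if self.diseases is None:
            from .cohort import triple_h_diseases

            return triple_h_diseases()
        return load_disease_config(
            [d.model_dump(mode="json") for d in self.diseases]
        )

    def generator_config(self, seed: int) -> GeneratorConfig:
        return GeneratorConfig(
            n_subjects=self.generator.n_subjects,
            seed=seed,
            disease_prevalence=self.generator.disease_prevalence,
            min_state_count=self.generator.min_state_count,
            max_retries=self.generator.max_retries,
        )


def load_run_config(path: str | Path | None) -> RunConfig:
    """Load and validate a RunConfig JSON; defaults when ``path`` is None."""
    if path is None:
        return RunConfig()
    try:
        with open(path, "r", encoding="utf-8") as fh:
            data = json.load(fh)
        return RunConfig.model_validate(data)
    except (OSError, json.JSONDecodeError) as exc:
        raise InputError(f"cannot read config {path}: {exc}") from exc
    except ValidationError as exc:
        raise InputError(f"invalid config {path}: {exc}") from exc
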