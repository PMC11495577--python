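"""Pipeline configuration.

One document configures every stage; unknown keys are rejected and all
defaults are the protocol values used throughout the package
(percentiles 25/75/50, extraction epsilon 1e-4, sampler 10000/100,
alpha 0.05, flux-change cutoff 0.82, diel photon 300, FVA fraction
0.8, cross-validation 10x10 with 500 K-best features).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ThresholdingSection(_Section):
    global_lower_pct: float = 25.0
    global_upper_pct: float = 75.0
    local_pct: float = 50.0


class ExtractionSection(_Section):
    epsilon: float = Field(1e-4, gt=0)
    missing_gene_value: float = 0.0  # missing expression = inactive


class SamplingSection(_Section):
    n: int = Field(10_000, ge=1)
    thinning: int = Field(100, ge=1)
    seed: int = 0


class DiffFluxSection(_Section):
    alpha: float = Field(0.05, gt=0, le=1)
    fc_threshold: float = Field(0.82, ge=0)
    n_boot: int = Field(1000, ge=1)
    require_fc: bool = True


class DielSection(_Section):
    photon_uptake: float = Field(300.0, ge=0)
    nitrate_light_dark_ratio: float = Field(1.5, gt=0)
    rubisco_ratio: float = Field(3.0, gt=0)


class StrategySection(_Section):
    biomass_value: float = Field(0.11, ge=0)
    photon_uptake: float = Field(100.0, ge=0)
    sucrose_uptake: float = Field(1.0, ge=0)


class FVASection(_Section):
    fraction_of_optimum: float = Field(0.8, gt=0, le=1)


class MLSection(_Section):
    n_folds: int = Field(10, ge=2)
    n_repeats: int = Field(10, ge=1)
    k_best: int = Field(500, ge=1)
    seed: int = 0
    positive_label: str = "mature"
    attribution_family: str = "random-forest"
    n_permutations: int = Field(8, ge=1)


class StagesSection(_Section):
    context: bool = True
    diel: bool = True
    diffflux: bool = True
    fluxml: bool = True


class PathsSection(_Section):
    model: str | None = None  # generic SBML; None -> synthetic toy
    expression: str | None = None
    metadata: str | None = None
    out_dir: str = "dielflux_out"


class PipelineConfig(_Section):
    seed: int = 0
    paths: PathsSection = Field(default_factory=PathsSection)
    stages: StagesSection = Field(default_factory=StagesSection)
    thresholding: ThresholdingSection = Field(default_factory=ThresholdingSection)
    extraction: ExtractionSection = Field(default_factory=ExtractionSection)
    sampling: SamplingSection = Field(default_factory=SamplingSection)
    diffflux: DiffFluxSection = Field(default_factory=DiffFluxSection)
    diel: DielSection = Field(default_factory=DielSection)
    strategy: StrategySection = Field(default_factory=StrategySection)
    fva: FVASection = Field(default_factory=FVASection)
    ml: MLSection = Field(default_factory=MLSection)

    def digest(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def validate_config(path: str | Path | None = None,
                    overrides: dict | None = None) -> PipelineConfig:
    """Load and validate a YAML/JSON config; empty file = all defaults."""
    data: dict = {}
    if path is not None:
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config root must be a mapping, got "
                             f"{type(data).__name__}")
    if overrides:
        data = _deep_merge(data, overrides)
    return PipelineConfig.model_validate(data)


def _deep_merge(base: dict, extra: dict) -> dict:
    out = dict(base)
    for key, value in extra.items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _deep_merge(out[key], value)
        else:
            out[key] = value
    return out
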