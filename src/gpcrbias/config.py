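"""Pipeline configuration: validated, serialisable, hashable for provenance."""

from __future__ import annotations

import hashlib
import json
from typing import Literal

import yaml
from pydantic import BaseModel, Field, field_validator

from .bias import BiasOptions
from .panels import ARRESTIN, GPROTEIN


class PipelineConfig(BaseModel):
    """Everything the CLI pipeline needs to be reproducible.

    The config is validated before any computation and its hash is embedded
    in every output file, so two runs with identical inputs, config and seed
    are numerically identical and identifiable as such.
    """

    references: dict[str, str] = Field(
        default_factory=lambda: {"MOR": "DAMGO", "KOR": "U50488h"},
        description="balanced reference agonist per receptor",
    )
    pathway_pair: tuple[str, str] = (GPROTEIN, ARRESTIN)
    hill_slope: float = 1.0
    per_experiment: bool = True
    biphasic_policy: Literal["mask", "fit-all"] = "mask"
    min_span_pct: float = 10.0
    min_snr: float = 3.0
    contact_cutoff_A: float = 4.5
    mpe_cutoff_s: float = 15.0
    peak_time_min: float = 10.0
    alpha: float = 0.05
    seed: int = 0
    outdir: str = "gpcrbias_out"

    @field_validator("min_span_pct", "min_snr", "contact_cutoff_A", "mpe_cutoff_s")
    @classmethod
    def _positive(cls, v):
        if v <= 0:
            raise ValueError("threshold must be positive")
        return v

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(json.loads(self.model_dump_json()), fh, sort_keys=True)

    @property
    def hash(self) -> str:
        canon = json.dumps(json.loads(self.model_dump_json()), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]

    def bias_options(self) -> BiasOptions:
        return BiasOptions(
            pathway_pair=self.pathway_pair,
            per_experiment=self.per_experiment,
            n_hill=self.hill_slope,
            min_span_pct=self.min_span_pct,
            min_snr=self.min_snr,
            biphasic_policy="mask" if self.biphasic_policy == "mask" else "fit-all",
            alpha=self.alpha,
        )
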