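"""Validated pipeline configuration (YAML-backed, documented in README)."""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, Field, field_validator, model_validator


class CohortSimConfig(BaseModel):
    n_patients: int = Field(300, ge=20)
    solo_per_oncogene: int = Field(30, ge=1)
    shared_per_pair: int = Field(15, ge=1)
    n_genes: int = Field(1500, ge=200)
    association_effect: float = 2.0
    signature_effect: float = 1.0
    noise_sigma: float = Field(0.5, gt=0)
    hazard_factor: float = Field(1.5, gt=0)
    myc_high_freq: float = Field(0.5, gt=0, lt=1)
    kras_mut_freq: float = Field(0.35, gt=0, lt=1)
    tp53_missense_freq: float = Field(0.35, gt=0, lt=1)


class SimulateConfig(BaseModel):
    n_genes: int = Field(2000, ge=10)
    pool_size: int = Field(400, ge=10)
    class_fractions: tuple[float, float, float] = (0.6, 0.3, 0.1)
    effect_size: float = Field(2.0, gt=0)
    dispersion: float = Field(0.02, ge=0)
    replicates: int = Field(3, ge=2)
    tissue: str = "colon"
    knockdown_efficiency: float = Field(1.0, gt=0, le=1)
    universal_targets: tuple[str, ...] = ("RUVBL1", "HSPA9", "XPO1")
    universal_effect: float = Field(3.0, gt=0)
    cohort: CohortSimConfig = CohortSimConfig()

    @model_validator(mode="after")
    def _fractions_sum(self):
        if abs(sum(self.class_fractions) - 1.0) > 1e-9:
            raise ValueError("class_fractions must sum to 1")
        return self


class Thresholds(BaseModel):
    mrna_fdr: float = 0.05
    protein_p: float = 0.05
    enrichment_p: float = 0.05
    association_fdr: float = 0.001

    @field_validator("mrna_fdr", "protein_p", "enrichment_p", "association_fdr")
    @classmethod
    def _open_unit_interval(cls, v: float) -> float:
        if not 0.0 < v < 1.0:
            raise ValueError(f"threshold must lie in (0, 1), got {v}")
        return v


class PathsConfig(BaseModel):
    """Optional externally supplied inputs; defaults point at the files the
    simulate stage writes into the run directory."""

    mrna_matrix: str = "mrna.tsv"
    protein_matrix: str = "protein.tsv"
    annotations: str = "samples.tsv"
    gene_sets: str = "genesets.gmt"
    coding_genes: str = "coding_genes.txt"
    cohort_expression: str = "cohort_expression.tsv"
    cohort_mutations: str = "cohort_mutations.tsv"
    cohort_survival: str = "cohort_survival.tsv"


class PipelineConfig(BaseModel):
    seed: int = Field(1, ge=0, lt=2**31)
    select_k: int = Field(3, ge=1)
    cohort_comparator: str = "control"
    simulate: SimulateConfig = SimulateConfig()
    thresholds: Thresholds = Thresholds()
    paths: PathsConfig = PathsConfig()

    @field_validator("cohort_comparator")
    @classmethod
    def _comparator(cls, v: str) -> str:
        if v not in ("rest", "control"):
            raise ValueError("cohort_comparator must be 'rest' or 'control'")
        return v


def load_config(path: str | Path | None) -> PipelineConfig:
    """Load and validate a YAML configuration (defaults when path is None)."""
    if path is None:
        return PipelineConfig()
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    return PipelineConfig.model_validate(raw)
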