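"""Run configuration: one schema-validated object holding every threshold.

Defaults encode the validated assay parameters: VAF limit of detection
0.05, >= 12 alt reads, population-AF cutoff 0.01, consensus 3-of-5 (SNV) /
3-of-6 (indel), and coverage pass rules 300x (somatic) / 200x (germline)
in at least 80% of target regions.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, Field, field_validator

from .classify import FilterConfig
from .consensus import DEFAULT_INDEL_CALLERS, DEFAULT_SNV_CALLERS, ConsensusConfig

__all__ = ["ConsensusSettings", "FilterSettings", "QCSettings", "RunConfig", "load_config"]


class ConsensusSettings(BaseModel):
    snv_caller_set: list[str] = list(DEFAULT_SNV_CALLERS)
    indel_caller_set: list[str] = list(DEFAULT_INDEL_CALLERS)
    min_support_snv: int = 3
    min_support_indel: int = 3
    count_nonpass_calls: bool = False
    vaf_aggregation: str = "median"
    primary_caller: Optional[str] = None

    def build(self) -> ConsensusConfig:
        return ConsensusConfig(
            snv_caller_set=tuple(self.snv_caller_set),
            indel_caller_set=tuple(self.indel_caller_set),
            min_support_snv=self.min_support_snv,
            min_support_indel=self.min_support_indel,
            count_nonpass_calls=self.count_nonpass_calls,
            vaf_aggregation=self.vaf_aggregation,
            primary_caller=self.primary_caller,
        )


class FilterSettings(BaseModel):
    min_vaf: float = 0.05
    min_alt_reads: int = 12
    max_pop_af: float = 0.01
    germline_vaf_bands: list[tuple[float, float]] = [(0.40, 0.60), (0.90, 1.00)]
    min_cosmic_count: int = 1
    local_db_in_pop_filter: bool = True
    rule_order: list[str] = ["R1", "R2", "R3", "R4", "R5", "R6"]

    def build(self) -> FilterConfig:
        return FilterConfig(
            min_vaf=self.min_vaf,
            min_alt_reads=self.min_alt_reads,
            max_pop_af=self.max_pop_af,
            germline_vaf_bands=tuple(tuple(b) for b in self.germline_vaf_bands),
            min_cosmic_count=self.min_cosmic_count,
            local_db_in_pop_filter=self.local_db_in_pop_filter,
            rule_order=tuple(self.rule_order),
        )


class QCSettings(BaseModel):
    mode: str = "somatic"
    thresholds: list[int] = [100, 200, 300, 400, 500]
    uniformity_factor: float = 0.2

    @field_validator("mode")
    @classmethod
    def _known_mode(cls, v: str) -> str:
        if v not in {"somatic", "germline"}:
            raise ValueError(f"unknown QC mode {v!r}")
        return v


class RunConfig(BaseModel):
    """Top-level pipeline configuration (YAML-loadable)."""

    consensus: ConsensusSettings = Field(default_factory=ConsensusSettings)
    filters: FilterSettings = Field(default_factory=FilterSettings)
    qc: QCSettings = Field(default_factory=QCSettings)
    kb_path: Optional[str] = None
    seed: int = 0


def load_config(path: str | Path | None) -> RunConfig:
    if path is None:
        return RunConfig()
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(data)
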