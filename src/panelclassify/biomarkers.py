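"""Actionable-biomarker matching and cohort summary statistics.

Somatic-category variants are matched against a static drug-evidence
knowledge base (gene- or protein-change-level rules, each with a drug, a
responsive/resistant effect, and an evidence tier ordered from FDA
guidelines down to pre-clinical data). Cohort summaries reproduce the
standard reporting shapes for a targeted panel: per-category variant
counts (total and unique), a gene x tumor-type mutation matrix with a
consequence breakdown, tier histograms, and concordance/correlation
statistics between runs or sample types.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .classify import Category, ClassifiedVariant, SOMATIC_FAMILY

__all__ = [
    "EvidenceTier",
    "BiomarkerRule",
    "BiomarkerHit",
    "load_knowledge_base",
    "match_biomarkers",
    "biomarker_fraction",
    "summarize_classification",
    "gene_tumor_matrix",
    "percent",
    "vaf_concordance",
    "set_concordance",
]


class EvidenceTier(enum.IntEnum):
    """Ordered evidence vocabulary; higher value = stronger evidence."""

    PRE_CLINICAL = 1
    CASE_REPORT = 2
    EARLY_TRIALS = 3
    LATE_TRIALS = 4
    CLINICAL_GUIDELINES = 5
    FDA_GUIDELINES = 6

    @classmethod
    def from_label(cls, label: str) -> "EvidenceTier":
        try:
            return cls[label.strip().upper()]
        except KeyError:
            raise ValueError(f"unknown evidence tier {label!r}") from None

    @property
    def label(self) -> str:
        return self.name.lower()


_EFFECTS = {"responsive", "resistant"}


@dataclass(frozen=True)
class BiomarkerRule:
    gene: str
    match_kind: str  # "exact_protein_change" | "gene_level"
    protein_change: str
    drug: str
    effect: str
    evidence_tier: EvidenceTier
    tumor_types: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.match_kind not in {"exact_protein_change", "gene_level"}:
            raise ValueError(f"unknown match_kind {self.match_kind!r}")
        if self.match_kind == "exact_protein_change" and not self.protein_change:
            raise ValueError("exact_protein_change rule requires a protein_change")
        if self.effect not in _EFFECTS:
            raise ValueError(f"unknown effect {self.effect!r}")


@dataclass(frozen=True)
class BiomarkerHit:
    sample_id: str
    variant_key: tuple[str, int, str, str]
    gene: str
    protein_change: str
    drug: str
    effect: str
    evidence_tier: EvidenceTier
    matched_by: str  # which rule kind produced the hit
    tumor_types: tuple[str, ...] = ()


def load_knowledge_base(path: str | Path) -> list[BiomarkerRule]:
    """Load the knowledge-base TSV.

    Columns: gene, match_kind, protein_change, drug, effect, evidence_tier,
    tumor_types (semicolon-joined). Duplicate (gene, protein_change, drug)
    rows are collapsed keeping the highest evidence tier.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, comment="#")
    best: dict[tuple[str, str, str], BiomarkerRule] = {}
    for _, row in df.iterrows():
        rule = BiomarkerRule(
            gene=row["gene"],
            match_kind=row["match_kind"],
            protein_change=row["protein_change"],
            drug=row["drug"],
            effect=row["effect"],
            evidence_tier=EvidenceTier.from_label(row["evidence_tier"]),
            tumor_types=tuple(filter(None, row.get("tumor_types", "").split(";"))),
        )
        key = (rule.gene, rule.protein_change, rule.drug)
        if key not in best or rule.evidence_tier > best[key].evidence_tier:
            best[key] = rule
    return list(best.values())


def match_biomarkers(
    classified_variants: Sequence[ClassifiedVariant],
    kb: Sequence[BiomarkerRule],
    somatic_only: bool = True,
) -> list[BiomarkerHit]:
    """Match classified variants against the knowledge base.

    Exact protein-change rules are applied first; gene-level rules apply to
    any protein-affecting variant in the gene. At most one hit per
    (variant occurrence, drug), kept at the highest supporting tier.
    Only somatic-family variants are eligible unless ``somatic_only`` is
    disabled.
    """
    exact: dict[tuple[str, str], list[BiomarkerRule]] = {}
    gene_level: dict[str, list[BiomarkerRule]] = {}
    for rule in kb:
        if rule.match_kind == "exact_protein_change":
            exact.setdefault((rule.gene, rule.protein_change), []).append(rule)
        else:
            gene_level.setdefault(rule.gene, []).append(rule)

    hits: list[BiomarkerHit] = []
    for cv in classified_variants:
        if somatic_only and cv.category not in SOMATIC_FAMILY:
            continue
        ann = cv.annotation
        best: dict[str, tuple[EvidenceTier, BiomarkerRule, str]] = {}

        def consider(rule: BiomarkerRule, kind: str) -> None:
            current = best.get(rule.drug)
            if current is None or rule.evidence_tier > current[0]:
                best[rule.drug] = (rule.evidence_tier, rule, kind)

        for rule in exact.get((ann.gene, ann.protein_change), []):
            consider(rule, "exact_protein_change")
        if ann.is_protein_affecting:
            for rule in gene_level.get(ann.gene, []):
                consider(rule, "gene_level")

        for drug in sorted(best):
            tier, rule, kind = best[drug]
            hits.append(
                BiomarkerHit(
                    sample_id=cv.sample_id,
                    variant_key=cv.consensus.variant.key,
                    gene=ann.gene,
                    protein_change=ann.protein_change,
                    drug=drug,
                    effect=rule.effect,
                    evidence_tier=tier,
                    matched_by=kind,
                    tumor_types=rule.tumor_types,
                )
            )
    return hits


def biomarker_fraction(
    classified_variants: Sequence[ClassifiedVariant], hits: Sequence[BiomarkerHit]
) -> float:
    """Fraction of somatic-family variant occurrences with >= 1 hit."""
    somatic = [
        (cv.sample_id, cv.consensus.variant.key)
        for cv in classified_variants
        if cv.category in SOMATIC_FAMILY
    ]
    if not somatic:
        return 0.0
    hit_keys = {(h.sample_id, h.variant_key) for h in hits}
    return sum(key in hit_keys for key in somatic) / len(somatic)


def summarize_classification(
    classified_variants: Sequence[ClassifiedVariant],
) -> pd.DataFrame:
    """Per-category total and unique variant counts, with a totals row.

    ``total`` counts variant occurrences across samples; ``unique`` counts
    distinct normalized genomic keys. All six categories appear even when
    empty.
    """
    totals = {c: 0 for c in Category}
    unique: dict[Category, set] = {c: set() for c in Category}
    for cv in classified_variants:
        totals[cv.category] += 1
        unique[cv.category].add(cv.consensus.variant.key)
    df = pd.DataFrame(
        {
            "category": [c.value for c in Category],
            "total": [totals[c] for c in Category],
            "unique": [len(unique[c]) for c in Category],
        }
    )
    grand = pd.DataFrame(
        {
            "category": ["total"],
            "total": [df["total"].sum()],
            "unique": [df["unique"].sum()],
        }
    )
    return pd.concat([df, grand], ignore_index=True)


@dataclass(frozen=True)
class GeneTumorMatrix:
    """Gene x tumor-type mutation counts with a consequence breakdown."""

    matrix: pd.DataFrame  # genes x tumor types
    by_consequence: pd.DataFrame  # (gene, consequence) x tumor types

    @property
    def gene_marginals(self) -> pd.Series:
        return self.matrix.sum(axis=1)

    @property
    def tumor_marginals(self) -> pd.Series:
        return self.matrix.sum(axis=0)

    @property
    def total(self) -> int:
        return int(self.matrix.to_numpy().sum())


def gene_tumor_matrix(
    classified_variants: Sequence[ClassifiedVariant],
    sample_meta: Mapping[str, str],
    somatic_only: bool = True,
    protein_affecting_only: bool = True,
) -> GeneTumorMatrix:
    """Count mutations per (gene, tumor type), stratified by consequence.

    ``sample_meta`` maps sample_id to tumor type; a variant from a sample
    without metadata is an error (all offending ids are listed).
    """
    eligible = [
        cv
        for cv in classified_variants
        if (not somatic_only or cv.category in SOMATIC_FAMILY)
        and (not protein_affecting_only or cv.annotation.is_protein_affecting)
    ]
    missing = sorted({cv.sample_id for cv in eligible} - set(sample_meta))
    if missing:
        raise KeyError(f"samples without tumor-type metadata: {missing}")

    rows = [
        {
            "gene": cv.annotation.gene,
            "tumor_type": sample_meta[cv.sample_id],
            "consequence": cv.annotation.consequence,
        }
        for cv in eligible
    ]
    if not rows:
        empty = pd.DataFrame()
        return GeneTumorMatrix(matrix=empty, by_consequence=empty)
    df = pd.DataFrame(rows)
    matrix = df.pivot_table(
        index="gene", columns="tumor_type", aggfunc="size", fill_value=0
    )
    by_consequence = df.pivot_table(
        index=["gene", "consequence"], columns="tumor_type", aggfunc="size", fill_value=0
    )
    return GeneTumorMatrix(matrix=matrix, by_consequence=by_consequence)


def percent(numerator: float, denominator: float, decimals: int = 0) -> float:
    """100 * n / d, rounded half-up to the requested decimals."""
    if denominator == 0:
        raise ZeroDivisionError("percent with zero denominator")
    value = Decimal(100) * Decimal(str(numerator)) / Decimal(str(denominator))
    quantum = Decimal(1).scaleb(-decimals)
    return float(value.quantize(quantum, rounding=ROUND_HALF_UP))


def vaf_concordance(paired_vafs: Iterable[tuple[float, float]]) -> tuple[float, int]:
    """Pearson correlation between paired VAF measurements."""
    pairs = np.asarray(list(paired_vafs), dtype=float)
    if pairs.ndim != 2 or pairs.shape[0] < 2:
        raise ValueError("need at least two finite VAF pairs")
    if not np.isfinite(pairs).all():
        raise ValueError("non-finite VAF values")
    x, y = pairs[:, 0], pairs[:, 1]
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in a VAF vector")
    r = stats.pearsonr(x, y).statistic
    return float(r), int(len(pairs))


@dataclass(frozen=True)
class SetConcordance:
    shared: int
    only_a: int
    only_b: int
    jaccard: float


def set_concordance(variants_a: Iterable, variants_b: Iterable) -> SetConcordance:
    """Overlap statistics on normalized variant keys."""
    a = {getattr(v, "key", v) for v in variants_a}
    b = {getattr(v, "key", v) for v in variants_b}
    shared = len(a & b)
    union = len(a | b)
    return SetConcordance(
        shared=shared,
        only_a=len(a - b),
        only_b=len(b - a),
        jaccard=shared / union if union else 0.0,
    )
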