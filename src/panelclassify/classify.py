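"""Detection-limit and population filters, tumor-only classification, and
germline hard filters.

Tumor-only panels cannot subtract a matched normal, so somatic status is
inferred from database evidence and the variant allele fraction (VAF).
The stages here mirror a clinical tumor-only pipeline:

1. detection-limit filter — drop calls below the assay's limit of
   detection (default VAF >= 0.05 and >= 12 alt reads);
2. population filter — drop common polymorphisms, taking the *maximum*
   allele frequency over every database **and** subpopulation (plus a
   local population database) so that under-represented populations are
   not missed (default: drop when max AF > 0.01, strict inequality);
3. six-category classification (germline, somatic, putative germline,
   putative somatic, putative novel germline, putative novel somatic)
   through an ordered first-match rule list driven by COSMIC, dbSNP,
   ClinVar, population-database and local-database evidence plus
   heterozygous/homozygous VAF bands;
4. an independent germline hard-filter stage (GATK-style per-class site
   thresholds) for the germline calling arm.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .annotations import AnnotationRecord
from .variants import ConsensusVariant

__all__ = [
    "Category",
    "SOMATIC_FAMILY",
    "GERMLINE_FAMILY",
    "FilterConfig",
    "FilterDecision",
    "ClassifiedVariant",
    "ClassificationError",
    "apply_detection_filters",
    "max_population_af",
    "apply_population_filter",
    "classify_variant",
    "GermlineHardFilterConfig",
    "apply_germline_hard_filters",
]


class Category(str, enum.Enum):
    GERMLINE = "germline"
    PUTATIVE_GERMLINE = "putative_germline"
    PUTATIVE_NOVEL_GERMLINE = "putative_novel_germline"
    SOMATIC = "somatic"
    PUTATIVE_SOMATIC = "putative_somatic"
    PUTATIVE_NOVEL_SOMATIC = "putative_novel_somatic"


#: Category families used for biomarker eligibility and recovery metrics.
SOMATIC_FAMILY = frozenset(
    {Category.SOMATIC, Category.PUTATIVE_SOMATIC, Category.PUTATIVE_NOVEL_SOMATIC}
)
GERMLINE_FAMILY = frozenset(
    {Category.GERMLINE, Category.PUTATIVE_GERMLINE, Category.PUTATIVE_NOVEL_GERMLINE}
)


class ClassificationError(RuntimeError):
    """A kept variant had no annotation record to classify against."""


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds for the filtering and classification stages.

    ``min_vaf`` is the assay limit of detection; ``germline_vaf_bands`` are
    the VAF windows consistent with heterozygous and homozygous germline
    genotypes in tumor tissue. ``clinvar_germline_markers`` are substrings
    of a ClinVar significance label that assert a germline condition.
    """

    min_vaf: float = 0.05
    min_alt_reads: int = 12
    max_pop_af: float = 0.01
    germline_vaf_bands: tuple[tuple[float, float], ...] = ((0.40, 0.60), (0.90, 1.00))
    min_cosmic_count: int = 1
    clinvar_germline_markers: tuple[str, ...] = ("germline",)
    local_db_in_pop_filter: bool = True
    rule_order: tuple[str, ...] = ("R1", "R2", "R3", "R4", "R5", "R6")

    def __post_init__(self) -> None:
        if not 0.0 < self.min_vaf < 1.0:
            raise ValueError(f"min_vaf {self.min_vaf} outside (0, 1)")
        bands = sorted(self.germline_vaf_bands)
        for lo, hi in bands:
            if not (0.0 <= lo <= hi <= 1.0):
                raise ValueError(f"band ({lo}, {hi}) outside [0, 1]")
        for (_, hi), (lo, _) in zip(bands, bands[1:]):
            if lo <= hi:
                raise ValueError("germline VAF bands must be disjoint")

    def in_germline_band(self, vaf: float) -> bool:
        return any(lo <= vaf <= hi for lo, hi in self.germline_vaf_bands)

    def clinvar_asserts_germline(self, clinvar_sig: Optional[str]) -> bool:
        if not clinvar_sig:
            return False
        label = clinvar_sig.lower()
        return any(marker in label for marker in self.clinvar_germline_markers)


@dataclass(frozen=True)
class FilterDecision:
    keep: bool
    reasons: tuple[str, ...] = ()

    def __bool__(self) -> bool:
        return self.keep


def apply_detection_filters(v: ConsensusVariant, cfg: FilterConfig) -> FilterDecision:
    """Keep iff VAF >= LOD and alt depth >= the minimum, both inclusive.

    Every failed criterion is reported, not only the first.
    """
    reasons = []
    if v.vaf < cfg.min_vaf:
        reasons.append("low_vaf")
    if v.alt_depth < cfg.min_alt_reads:
        reasons.append("low_alt_depth")
    return FilterDecision(keep=not reasons, reasons=tuple(reasons))


def max_population_af(ann: AnnotationRecord, include_local: bool = True) -> Optional[float]:
    """Maximum AF over every (database, subpopulation) entry, and the local
    database when ``include_local``; ``None`` when no entry exists anywhere."""
    values = list(ann.pop_afs.values())
    if include_local and ann.local_db_af is not None:
        values.append(ann.local_db_af)
    return max(values) if values else None


def apply_population_filter(
    v: ConsensusVariant, ann: AnnotationRecord, cfg: FilterConfig
) -> FilterDecision:
    """Drop common polymorphisms: max population AF strictly greater than
    the cutoff (an AF exactly at the cutoff is kept)."""
    max_af = max_population_af(ann, include_local=cfg.local_db_in_pop_filter)
    if max_af is not None and max_af > cfg.max_pop_af:
        return FilterDecision(keep=False, reasons=("common_polymorphism",))
    return FilterDecision(keep=True)


@dataclass(frozen=True)
class ClassifiedVariant:
    consensus: ConsensusVariant
    annotation: AnnotationRecord
    category: Category
    rule_trail: tuple[str, ...]

    @property
    def sample_id(self) -> str:
        return self.consensus.sample_id

    @property
    def is_somatic_family(self) -> bool:
        return self.category in SOMATIC_FAMILY


def _classification_rules(
    v: ConsensusVariant, ann: AnnotationRecord, cfg: FilterConfig
) -> Mapping[str, Optional[Category]]:
    """Evaluate each rule's firing condition on one variant.

    The rules form a decision list: each states its *minimal* positive
    condition and relies on list order for exclusions (e.g. R3 reached
    after R2 implies dbSNP/PVD presence). This is what makes the order a
    real degree of freedom — permuting R4 and R5, say, changes the label
    of a dbSNP-known variant inside a germline VAF band.
    """
    has_cosmic = ann.cosmic_count >= cfg.min_cosmic_count
    has_pvd_or_dbsnp = ann.has_pvd_entry or ann.dbsnp_id is not None
    in_band = cfg.in_germline_band(v.vaf)
    germline_evidence = (
        cfg.clinvar_asserts_germline(ann.clinvar_sig) or ann.local_db_af is not None
    )
    return {
        # direct germline assertion (ClinVar condition / local database)
        "R1": Category.GERMLINE if germline_evidence else None,
        # COSMIC-recurrent, absent from every germline resource
        "R2": Category.SOMATIC if has_cosmic and not has_pvd_or_dbsnp else None,
        # COSMIC-recurrent with a VAF inconsistent with germline genotypes
        "R3": Category.PUTATIVE_SOMATIC if has_cosmic and not in_band else None,
        # known to germline resources, VAF in a het/hom band
        "R4": Category.PUTATIVE_GERMLINE if has_pvd_or_dbsnp and in_band else None,
        # known to germline resources but VAF says otherwise
        "R5": Category.PUTATIVE_SOMATIC if has_pvd_or_dbsnp else None,
        # no database evidence at all: novel, split purely on VAF
        "R6": Category.PUTATIVE_NOVEL_GERMLINE if in_band else Category.PUTATIVE_NOVEL_SOMATIC,
    }


def classify_variant(
    v: ConsensusVariant, ann: Optional[AnnotationRecord], cfg: FilterConfig
) -> ClassifiedVariant:
    """Assign one of the six origin categories by an ordered rule list.

    First match wins, following ``cfg.rule_order``; the trail of rules
    consulted is recorded so every assignment is auditable. The default
    ordering encodes the evidence hierarchy: direct germline assertions
    (ClinVar condition, local-database presence) outrank COSMIC
    recurrence, which outranks population-database / dbSNP presence, with
    the VAF bands breaking ties; variants with no database evidence at
    all are "novel" and split purely on VAF.
    """
    if ann is None:
        raise ClassificationError(f"no annotation for kept variant {v.variant}")

    outcomes = _classification_rules(v, ann, cfg)
    unknown = set(cfg.rule_order) - set(outcomes)
    if unknown:
        raise ValueError(f"unknown rule ids in rule_order: {sorted(unknown)}")

    trail: list[str] = []
    for rule_id in cfg.rule_order:
        category = outcomes[rule_id]
        if category is not None:
            trail.append(f"{rule_id}_fired")
            return ClassifiedVariant(v, ann, category, tuple(trail))
        trail.append(f"{rule_id}_no_match")
    raise ClassificationError(
        f"no rule fired for {v.variant}; rule_order {cfg.rule_order} lacks a fallback"
    )


# ---------------------------------------------------------------------------
# Germline arm: GATK-style per-class site hard filters
# ---------------------------------------------------------------------------

_SNP_THRESHOLDS: Mapping[str, tuple[str, float]] = {
    "QD": ("lt", 2.0),
    "FS": ("gt", 60.0),
    "MQ": ("lt", 40.0),
    "MQRankSum": ("lt", -12.5),
    "ReadPosRankSum": ("lt", -8.0),
}
_INDEL_THRESHOLDS: Mapping[str, tuple[str, float]] = {
    "QD": ("lt", 2.0),
    "FS": ("gt", 200.0),
    "ReadPosRankSum": ("lt", -20.0),
}


@dataclass(frozen=True)
class GermlineHardFilterConfig:
    """Site-level hard filters for the germline calling arm.

    A metric fails when it is below ("lt") or above ("gt") its bound;
    metrics absent from a record are never violations.
    """

    min_qual: float = 30.0
    snp_thresholds: Mapping[str, tuple[str, float]] = field(
        default_factory=lambda: dict(_SNP_THRESHOLDS)
    )
    indel_thresholds: Mapping[str, tuple[str, float]] = field(
        default_factory=lambda: dict(_INDEL_THRESHOLDS)
    )


def apply_germline_hard_filters(
    site_metrics: Mapping[str, float],
    variant_class: str,
    cfg: GermlineHardFilterConfig | None = None,
) -> FilterDecision:
    """Pass/fail a germline site against QUAL and per-class metric bounds.

    ``site_metrics`` carries ``qual`` plus any of QD, FS, MQ, MQRankSum,
    ReadPosRankSum. ``variant_class`` is ``"snp"`` or ``"indel"``.
    """
    cfg = cfg or GermlineHardFilterConfig()
    if variant_class == "snp":
        thresholds = cfg.snp_thresholds
    elif variant_class == "indel":
        thresholds = cfg.indel_thresholds
    else:
        raise ValueError(f"unknown variant class {variant_class!r}")

    reasons = []
    qual = site_metrics.get("qual")
    if qual is not None and qual < cfg.min_qual:
        reasons.append("low_qual")
    for metric, (direction, bound) in thresholds.items():
        value = site_metrics.get(metric)
        if value is None:
            continue
        if (direction == "lt" and value < bound) or (direction == "gt" and value > bound):
            reasons.append(metric)
    return FilterDecision(keep=not reasons, reasons=tuple(reasons))


def run_filters_and_classify(
    variants: Sequence[ConsensusVariant],
    annotations: Mapping[tuple, AnnotationRecord],
    cfg: FilterConfig,
) -> tuple[list[ClassifiedVariant], list[tuple[ConsensusVariant, tuple[str, ...]]]]:
    """Filter a consensus call set and classify the survivors.

    Returns ``(classified, dropped)`` where ``dropped`` pairs each removed
    variant with its drop reasons. Filtering precedes classification:
    only variants passing both the detection-limit and population filters
    are categorized.
    """
    classified: list[ClassifiedVariant] = []
    dropped: list[tuple[ConsensusVariant, tuple[str, ...]]] = []
    for v in variants:
        ann = annotations.get(v.variant.key)
        decision = apply_detection_filters(v, cfg)
        if decision.keep and ann is not None:
            pop = apply_population_filter(v, ann, cfg)
            if not pop.keep:
                decision = FilterDecision(False, decision.reasons + pop.reasons)
        if not decision.keep:
            dropped.append((v, decision.reasons))
            continue
        classified.append(classify_variant(v, ann, cfg))
    return classified, dropped
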