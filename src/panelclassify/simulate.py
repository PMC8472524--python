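"""Synthetic multi-caller cohorts with known ground truth.

Simulation starts at caller-output level (no reads): each truth variant
gets a Poisson sequencing depth and a binomial alt-read count at its true
VAF, and each caller independently detects it with a logistic probability
in the realized VAF. Germline heterozygous/homozygous variants sit in the
canonical VAF bands, somatic variants follow a VAF grid spanning the
assay's validated range, and FFPE artifacts are C>T/G>A substitutions at
VAFs well below the limit of detection (the deamination regime). Database
profiles are generated to be unambiguous by default, so end-to-end
classification against the generated annotation table is exactly
recoverable and the simulator can serve as a truth oracle for the whole
pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .annotations import AnnotationRecord
from .classify import Category, ClassifiedVariant, GERMLINE_FAMILY, SOMATIC_FAMILY
from .io import write_annotation_table, write_caller_vcf
from .variants import CallerCall, GenomicVariant, TargetRegion, VariantClass

__all__ = [
    "PANEL_GENES",
    "TruthVariant",
    "CallerDetectionModel",
    "CohortConfig",
    "Cohort",
    "generate_cohort",
    "hd_like_truth_set",
    "RecoveryMetrics",
    "recovery_metrics",
]

#: The 25 panel genes; synthetic coordinates place each gene on one
#: contig as a block of contiguous target regions.
PANEL_GENES: tuple[str, ...] = (
    "AKT1", "ALK", "ARID1A", "BRAF", "BRCA1", "BRCA2", "CDK4", "EGFR",
    "ERBB2", "ESR1", "IDH2", "KIT", "KRAS", "MET", "MTOR", "NRAS",
    "PDGFRA", "PIK3CA", "PTCH1", "PTEN", "ROS1", "SMO", "TP53", "TSC1",
    "TSC2",
)

_REGIONS_PER_GENE = 4
_REGION_LENGTH = 250  # bp per target region
_GENE_SPACING = 100_000

ORIGINS = ("germline_het", "germline_hom", "somatic", "ffpe_artifact")
PROFILES = ("cosmic_only", "pvd_rare", "pvd_common", "local_db", "novel")

#: truth origin -> family of acceptable assigned categories
ORIGIN_FAMILY: Mapping[str, frozenset] = {
    "germline_het": GERMLINE_FAMILY,
    "germline_hom": GERMLINE_FAMILY,
    "somatic": SOMATIC_FAMILY,
    "ffpe_artifact": SOMATIC_FAMILY,  # if one slipped through it would look somatic
}


def panel_regions() -> list[TargetRegion]:
    """Synthetic target regions: 4 x 250 bp per gene, one block per gene."""
    regions = []
    for i, gene in enumerate(PANEL_GENES):
        chrom = f"chr{i % 4 + 1}"
        base = (i + 1) * _GENE_SPACING
        for j in range(_REGIONS_PER_GENE):
            start = base + j * _REGION_LENGTH
            regions.append(TargetRegion(chrom, start, start + _REGION_LENGTH, gene))
    return regions


@dataclass(frozen=True)
class TruthVariant:
    sample_id: str
    variant: GenomicVariant
    true_origin: str
    true_vaf: float
    database_profile: str
    gene: str

    def __post_init__(self) -> None:
        if self.true_origin not in ORIGINS:
            raise ValueError(f"unknown origin {self.true_origin!r}")
        if self.database_profile not in PROFILES:
            raise ValueError(f"unknown profile {self.database_profile!r}")
        if self.true_origin == "germline_het" and not 0.40 <= self.true_vaf <= 0.60:
            raise ValueError("germline_het true VAF outside [0.40, 0.60]")
        if self.true_origin == "germline_hom" and not 0.90 <= self.true_vaf <= 1.00:
            raise ValueError("germline_hom true VAF outside [0.90, 1.00]")
        if self.true_origin == "ffpe_artifact":
            if self.true_vaf >= 0.05 or not self.variant.is_transition_ct_ga:
                raise ValueError("ffpe_artifact must be C>T/G>A below VAF 0.05")


@dataclass(frozen=True)
class CallerDetectionModel:
    """Per-caller logistic detection probability in the realized VAF.

    p(vaf) = 1 / (1 + exp(-slope * (vaf - midpoint))); ``detect_prob``
    overrides the logistic with a flat probability for every caller
    (1.0 reproduces the deterministic everything-detected regime).
    """

    midpoints: Mapping[str, float] = field(
        default_factory=lambda: {
            "mutect2": 0.015,
            "varscan2": 0.025,
            "vardict": 0.020,
            "lofreq": 0.015,
            "strelka": 0.030,
            "scalpel": 0.030,
        }
    )
    slope: float = 200.0
    detect_prob: Optional[float] = None

    def probability(self, caller_id: str, vaf: float) -> float:
        if self.detect_prob is not None:
            return self.detect_prob
        midpoint = self.midpoints.get(caller_id, 0.02)
        return 1.0 / (1.0 + math.exp(-self.slope * (vaf - midpoint)))


@dataclass(frozen=True)
class CohortConfig:
    """Study-condition knobs for the generator (seed is mandatory)."""

    seed: int
    n_samples: int = 8
    counts_per_origin: Mapping[str, int] = field(
        default_factory=lambda: {
            "germline_het": 10,
            "germline_hom": 3,
            "somatic": 12,
            "ffpe_artifact": 4,
        }
    )
    somatic_vaf_grid: tuple[float, ...] = (0.01, 0.02, 0.05, 0.10, 0.25, 0.50)
    artifact_vaf_range: tuple[float, float] = (0.005, 0.025)
    mean_depth: float = 500.0
    depth_cv: float = 0.10  # per-region QC depth spread
    indel_fraction: float = 0.2  # of somatic variants
    detection: CallerDetectionModel = field(default_factory=CallerDetectionModel)
    profile_by_origin: Mapping[str, str] = field(
        default_factory=lambda: {
            "germline_het": "local_db",
            "germline_hom": "local_db",
            "somatic": "cosmic_only",
            "ffpe_artifact": "novel",
        }
    )
    snv_callers: tuple[str, ...] = ("mutect2", "varscan2", "vardict", "lofreq", "strelka")
    indel_extra_callers: tuple[str, ...] = ("scalpel",)
    tumor_types: tuple[str, ...] = ("breast", "ovary", "colorectal", "gallbladder")

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("need at least one sample")
        if any(n < 0 for n in self.counts_per_origin.values()):
            raise ValueError("per-origin counts must be >= 0")
        if self.mean_depth <= 0:
            raise ValueError("mean depth must be positive")

    @property
    def all_callers(self) -> tuple[str, ...]:
        return self.snv_callers + self.indel_extra_callers


@dataclass
class Cohort:
    """In-memory cohort; ``write`` materializes the standard file layout."""

    config: CohortConfig
    truth: pd.DataFrame  # one row per (sample, variant)
    caller_calls: dict[tuple[str, str], list[CallerCall]]  # (sample, caller) -> calls
    annotations: list[AnnotationRecord]
    region_depths: dict[str, pd.DataFrame]  # sample -> chrom/start/end/mean_depth
    sample_meta: pd.DataFrame  # sample_id, tumor_type
    targets: list[TargetRegion]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.sample_meta["sample_id"])

    def write(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        (out / "depths").mkdir(parents=True, exist_ok=True)
        (out / "vcf").mkdir(exist_ok=True)
        self.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
        self.sample_meta.to_csv(out / "samples.tsv", sep="\t", index=False)
        write_annotation_table(self.annotations, out / "annotations.tsv")
        with open(out / "targets.bed", "w") as fh:
            for region in self.targets:
                fh.write(f"{region.chrom}\t{region.start}\t{region.end}\t{region.name}\n")
        for sample in self.sample_ids:
            self.region_depths[sample].to_csv(
                out / "depths" / f"{sample}.regions.tsv", sep="\t", index=False, header=False
            )
            for caller in self.config.all_callers:
                calls = self.caller_calls.get((sample, caller), [])
                write_caller_vcf(calls, out / "vcf" / f"{sample}.{caller}.vcf", sample)
        return out


def _draw_variant(
    rng: np.random.Generator,
    used: set[tuple[str, int]],
    origin: str,
    is_indel: bool,
) -> tuple[GenomicVariant, str]:
    """Place a variant at an unused position inside a random target region."""
    regions = panel_regions()
    bases = np.array(list("ACGT"))
    while True:
        region = regions[rng.integers(len(regions))]
        pos = int(rng.integers(region.start + 2, region.end - 2)) + 1  # 1-based
        if (region.chrom, pos) in used:
            continue
        used.add((region.chrom, pos))
        gene = region.name
        if origin == "ffpe_artifact":
            ref, alt = ("C", "T") if rng.random() < 0.5 else ("G", "A")
        elif is_indel:
            anchor = str(bases[rng.integers(4)])
            inserted = str(bases[rng.integers(4)])
            if rng.random() < 0.5:
                ref, alt = anchor, anchor + inserted  # insertion
            else:
                ref, alt = anchor + inserted, anchor  # deletion
        else:
            ref = str(bases[rng.integers(4)])
            alt = str(bases[(int(np.where(bases == ref)[0][0]) + int(rng.integers(1, 4))) % 4])
        return GenomicVariant(region.chrom, pos, ref, alt), gene


def _annotation_for(
    rng: np.random.Generator, variant: GenomicVariant, gene: str, profile: str
) -> AnnotationRecord:
    consequence = str(rng.choice(["missense", "nonsense", "frameshift_del", "splice_site"]))
    if variant.variant_class is VariantClass.INDEL:
        consequence = "frameshift_del" if len(variant.ref) > len(variant.alt) else "frameshift_ins"
    protein_change = f"{rng.choice(list('ACDEFGHIKLMNPQRSTVWY'))}{rng.integers(10, 999)}" + str(
        rng.choice(list("ACDEFGHIKLMNPQRSTVWY"))
    )
    kwargs: dict = {}
    if profile == "cosmic_only":
        kwargs.update(
            cosmic_id=f"COSV{rng.integers(10_000, 99_999)}",
            cosmic_count=int(rng.integers(2, 60)),
        )
    elif profile == "pvd_rare":
        kwargs.update(
            dbsnp_id=f"rs{rng.integers(10_000_000, 99_999_999)}",
            pop_afs={
                ("gnomad_genome", "ALL"): float(rng.uniform(0.0005, 0.009)),
                ("gnomad_genome", "AMR"): float(rng.uniform(0.0005, 0.009)),
            },
        )
    elif profile == "pvd_common":
        kwargs.update(
            dbsnp_id=f"rs{rng.integers(10_000_000, 99_999_999)}",
            pop_afs={
                ("gnomad_genome", "ALL"): float(rng.uniform(0.02, 0.30)),
                ("g1000", "ALL"): float(rng.uniform(0.02, 0.30)),
            },
        )
    elif profile == "local_db":
        kwargs.update(
            local_db_af=float(rng.uniform(0.001, 0.009)),
            clinvar_sig="germline",
        )
    # "novel": no database evidence at all
    return AnnotationRecord(
        variant=variant,
        gene=gene,
        consequence=consequence,
        protein_change=protein_change,
        **kwargs,
    )


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate a deterministic cohort for a fixed seed."""
    rng = np.random.default_rng(config.seed)
    used_positions: set[tuple[str, int]] = set()
    truth_rows = []
    caller_calls: dict[tuple[str, str], list[CallerCall]] = {}
    annotations: dict[tuple, AnnotationRecord] = {}
    region_depths: dict[str, pd.DataFrame] = {}
    targets = panel_regions()

    sample_ids = [f"S{i + 1:03d}" for i in range(config.n_samples)]
    meta = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "tumor_type": [
                config.tumor_types[i % len(config.tumor_types)]
                for i in range(config.n_samples)
            ],
        }
    )

    for sample in sample_ids:
        for caller in config.all_callers:
            caller_calls[(sample, caller)] = []
        somatic_index = 0
        for origin in ORIGINS:
            for _ in range(config.counts_per_origin.get(origin, 0)):
                if origin == "germline_het":
                    true_vaf = float(rng.uniform(0.40, 0.60))
                elif origin == "germline_hom":
                    true_vaf = float(rng.uniform(0.90, 1.00))
                elif origin == "somatic":
                    grid = config.somatic_vaf_grid
                    true_vaf = float(grid[somatic_index % len(grid)])
                    somatic_index += 1
                else:  # ffpe_artifact
                    true_vaf = float(rng.uniform(*config.artifact_vaf_range))
                is_indel = origin == "somatic" and rng.random() < config.indel_fraction
                variant, gene = _draw_variant(rng, used_positions, origin, is_indel)
                profile = config.profile_by_origin[origin]
                annotations[variant.key] = _annotation_for(rng, variant, gene, profile)
                truth_rows.append(
                    {
                        "sample_id": sample,
                        "chrom": variant.chrom,
                        "pos": variant.pos,
                        "ref": variant.ref,
                        "alt": variant.alt,
                        "true_origin": origin,
                        "true_vaf": true_vaf,
                        "database_profile": profile,
                        "gene": gene,
                    }
                )

                # one sequencing realization per variant, shared by callers
                depth = max(int(rng.poisson(config.mean_depth)), 1)
                alt_depth = int(rng.binomial(depth, true_vaf))
                realized_vaf = alt_depth / depth
                if alt_depth == 0:
                    continue
                callers = (
                    config.snv_callers
                    if variant.variant_class is VariantClass.SNV
                    else config.snv_callers + config.indel_extra_callers
                )
                for caller in callers:
                    p = config.detection.probability(caller, realized_vaf)
                    if rng.random() < p:
                        caller_calls[(sample, caller)].append(
                            CallerCall(
                                variant=variant,
                                caller_id=caller,
                                vaf=realized_vaf,
                                alt_depth=alt_depth,
                                total_depth=depth,
                            )
                        )

        depths = rng.normal(
            config.mean_depth, config.depth_cv * config.mean_depth, size=len(targets)
        ).clip(min=0.0)
        region_depths[sample] = pd.DataFrame(
            {
                "chrom": [t.chrom for t in targets],
                "start": [t.start for t in targets],
                "end": [t.end for t in targets],
                "mean_depth": np.round(depths, 2),
            }
        )

    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "sample_id", "chrom", "pos", "ref", "alt",
            "true_origin", "true_vaf", "database_profile", "gene",
        ],
    )
    return Cohort(
        config=config,
        truth=truth,
        caller_calls=caller_calls,
        annotations=list(annotations.values()),
        region_depths=region_depths,
        sample_meta=meta,
        targets=targets,
    )


def hd_like_truth_set(
    n_variants: int, vaf_range: tuple[float, float], seed: int = 0
) -> pd.DataFrame:
    """A reference-standard-like truth set: VAFs spanning the range endpoints.

    Mimics a characterized control sample with known variants across a VAF
    ladder (an analog, not a replica of any commercial standard), for
    expected-vs-observed correlation checks.
    """
    if n_variants < 1:
        raise ValueError("need at least one variant")
    lo, hi = vaf_range
    if not (0.0 < lo <= hi <= 1.0):
        raise ValueError(f"bad VAF range {vaf_range}")
    vafs = [0.5 * (lo + hi)] if n_variants == 1 else list(np.linspace(lo, hi, n_variants))
    rng = np.random.default_rng(seed)
    used: set[tuple[str, int]] = set()
    rows = []
    for i, vaf in enumerate(vafs):
        variant, gene = _draw_variant(rng, used, "somatic", is_indel=False)
        rows.append(
            {
                "sample_id": "HD_LIKE",
                "chrom": variant.chrom,
                "pos": variant.pos,
                "ref": variant.ref,
                "alt": variant.alt,
                "true_origin": "somatic",
                "true_vaf": float(vaf),
                "database_profile": "cosmic_only",
                "gene": gene,
            }
        )
    return pd.DataFrame(rows)


def realize_vafs(truth: pd.DataFrame, mean_depth: float, seed: int) -> pd.DataFrame:
    """Simulate one sequencing measurement of a truth set.

    Adds ``depth``, ``alt_depth`` and ``observed_vaf`` columns: depth is
    Poisson around ``mean_depth`` and the alt count binomial at the true
    VAF — the counting-noise model under which observed VAFs concentrate
    around truth as depth grows.
    """
    rng = np.random.default_rng(seed)
    depths = np.maximum(rng.poisson(mean_depth, size=len(truth)), 1)
    alts = rng.binomial(depths, truth["true_vaf"].to_numpy())
    out = truth.copy()
    out["depth"] = depths
    out["alt_depth"] = alts
    out["observed_vaf"] = alts / depths
    return out


@dataclass(frozen=True)
class RecoveryMetrics:
    confusion: pd.DataFrame  # true_origin x (categories + absent)
    somatic_sensitivity: float
    germline_sensitivity: float
    family_recovery: float
    n_artifacts_in_output: int


def recovery_metrics(
    truth: pd.DataFrame, classified: Sequence[ClassifiedVariant]
) -> RecoveryMetrics:
    """Confusion table and family-level recovery of the truth labels.

    Sensitivities are conditional on detectability: the denominator is the
    set of truth variants of that family that survived consensus and
    filtering (i.e. appear in the classified output), so the numbers
    measure the classifier rather than binomial sampling noise.
    ``family_recovery`` is the fraction of classified truth variants whose
    assigned category family matches their true origin's family.
    """
    if truth.empty:
        raise ValueError("empty truth table")
    assigned: dict[tuple, str] = {
        (cv.sample_id, *cv.consensus.variant.key): cv.category.value for cv in classified
    }
    truth_keys = {
        (row.sample_id, row.chrom, int(row.pos), row.ref, row.alt)
        for row in truth.itertuples()
    }
    if classified and truth_keys.isdisjoint(assigned):
        raise ValueError("truth and classified share no variant keys")

    categories = [c.value for c in Category] + ["absent"]
    counts = {origin: {c: 0 for c in categories} for origin in ORIGINS}
    family_hits = family_total = 0
    som_hit = som_total = germ_hit = germ_total = 0
    n_artifacts = 0
    for row in truth.itertuples():
        key = (row.sample_id, row.chrom, int(row.pos), row.ref, row.alt)
        category = assigned.get(key, "absent")
        counts[row.true_origin][category] += 1
        if category == "absent":
            continue
        if row.true_origin == "ffpe_artifact":
            n_artifacts += 1
            continue
        family_total += 1
        match = Category(category) in ORIGIN_FAMILY[row.true_origin]
        family_hits += match
        if row.true_origin == "somatic":
            som_total += 1
            som_hit += match
        else:
            germ_total += 1
            germ_hit += match

    confusion = pd.DataFrame(counts).T.loc[list(ORIGINS), categories]
    return RecoveryMetrics(
        confusion=confusion,
        somatic_sensitivity=som_hit / som_total if som_total else 0.0,
        germline_sensitivity=germ_hit / germ_total if germ_total else 0.0,
        family_recovery=family_hits / family_total if family_total else 0.0,
        n_artifacts_in_output=n_artifacts,
    )
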