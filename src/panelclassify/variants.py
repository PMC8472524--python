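"""Core genomic-variant types and allele normalization.

Five somatic callers (plus Scalpel for indels) emit the same event in
different representations — padded alleles, un-trimmed indels, multi-allelic
records. Everything downstream (consensus voting, annotation joins,
biomarker matching) keys on the *minimal* normalized representation, so the
trimming rules here are the contract the whole toolkit rests on.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

__all__ = [
    "VariantError",
    "InvalidVariantError",
    "VariantFormatError",
    "VariantClass",
    "GenomicVariant",
    "CallerCall",
    "ConsensusVariant",
    "TargetRegion",
    "normalize_variant",
    "merge_regions",
]

_ALLELE_ALPHABET = frozenset("ACGTN")


class VariantError(ValueError):
    """Base class for variant representation problems."""


class InvalidVariantError(VariantError):
    """REF and ALT describe no change (equal after trimming)."""


class VariantFormatError(VariantError):
    """Allele strings contain characters outside A, C, G, T, N."""


class VariantClass(str, enum.Enum):
    SNV = "snv"
    INDEL = "indel"


@dataclass(frozen=True, order=True)
class GenomicVariant:
    """A normalized variant: 1-based position, minimal REF/ALT alleles."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise VariantFormatError(f"position must be >= 1, got {self.pos}")
        for allele in (self.ref, self.alt):
            if not allele or set(allele) - _ALLELE_ALPHABET:
                raise VariantFormatError(f"bad allele {allele!r}")
        if self.ref == self.alt:
            raise InvalidVariantError(f"ref == alt ({self.ref!r}) at {self.chrom}:{self.pos}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def variant_class(self) -> VariantClass:
        if len(self.ref) == 1 and len(self.alt) == 1:
            return VariantClass.SNV
        return VariantClass.INDEL

    @property
    def is_transition_ct_ga(self) -> bool:
        """C>T / G>A substitution — the FFPE deamination signature."""
        return (self.ref, self.alt) in {("C", "T"), ("G", "A")}

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:{self.pos}{self.ref}>{self.alt}"


def normalize_variant(chrom: str, pos: int, ref: str, alt: str) -> GenomicVariant:
    """Reduce ``(pos, ref, alt)`` to its minimal anchored representation.

    Shared trailing bases are trimmed first, then shared leading bases with
    the position advanced; one anchor base is retained whenever either
    allele would otherwise become empty (the VCF indel convention).
    Idempotent: normalizing a normalized variant is a no-op.

    Raises
    ------
    InvalidVariantError
        If REF equals ALT (before or after trimming).
    VariantFormatError
        For empty alleles, non-ACGTN characters, or pos < 1.
    """
    ref = str(ref).upper()
    alt = str(alt).upper()
    if not ref or not alt:
        raise VariantFormatError("empty allele")
    for allele in (ref, alt):
        if set(allele) - _ALLELE_ALPHABET:
            raise VariantFormatError(f"non-ACGTN characters in allele {allele!r}")
    if ref == alt:
        raise InvalidVariantError(f"ref == alt ({ref!r}) at {chrom}:{pos}")

    # trailing first, keeping at least one base on each side
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    # then leading, advancing pos, again keeping the anchor base
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return GenomicVariant(chrom=chrom, pos=int(pos), ref=ref, alt=alt)


@dataclass(frozen=True)
class CallerCall:
    """One variant observation from one named caller."""

    variant: GenomicVariant
    caller_id: str
    vaf: float
    alt_depth: int
    total_depth: int
    passed_caller_filter: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.vaf <= 1.0:
            raise ValueError(f"VAF {self.vaf} outside [0, 1]")
        if self.alt_depth < 0 or self.alt_depth > self.total_depth:
            raise ValueError(
                f"alt_depth {self.alt_depth} outside [0, total_depth={self.total_depth}]"
            )

    @property
    def variant_class(self) -> VariantClass:
        return self.variant.variant_class


@dataclass(frozen=True)
class ConsensusVariant:
    """A variant supported by enough callers, with aggregated VAF/depths."""

    variant: GenomicVariant
    supporting_callers: frozenset[str]
    vaf: float
    alt_depth: int
    total_depth: int
    sample_id: str = ""

    @property
    def n_support(self) -> int:
        return len(self.supporting_callers)

    @property
    def variant_class(self) -> VariantClass:
        return self.variant.variant_class


@dataclass(frozen=True, order=True)
class TargetRegion:
    """A panel target interval, BED-style 0-based half-open."""

    chrom: str
    start: int
    end: int
    name: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"start {self.start} >= end {self.end} ({self.chrom})")

    @property
    def length(self) -> int:
        return self.end - self.start


def merge_regions(regions: list[TargetRegion]) -> list[TargetRegion]:
    """Sort and merge overlapping/adjacent intervals per chromosome."""
    merged: list[TargetRegion] = []
    for region in sorted(regions):
        if merged and merged[-1].chrom == region.chrom and region.start <= merged[-1].end:
            last = merged.pop()
            merged.append(
                TargetRegion(last.chrom, last.start, max(last.end, region.end), last.name)
            )
        else:
            merged.append(region)
    return merged
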