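"""Multi-caller consensus ("majority vote") merging.

An ensemble of SNV callers (default five: Mutect2, VarScan2, VarDict,
LoFreq, Strelka) plus an indel-capable sixth (Scalpel) each emit a call
set; a variant is reported only when enough callers agree — by default at
least 3 of the 5 SNV callers for SNVs and at least 3 of the 6 callers for
indels. Only calls passing each caller's own filter count as support
unless configured otherwise.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .variants import CallerCall, ConsensusVariant, GenomicVariant, VariantClass

__all__ = [
    "DEFAULT_SNV_CALLERS",
    "DEFAULT_INDEL_CALLERS",
    "ConsensusConfig",
    "ConsensusConfigError",
    "merge_callers",
    "aggregate_vaf",
]

DEFAULT_SNV_CALLERS: tuple[str, ...] = (
    "mutect2",
    "varscan2",
    "vardict",
    "lofreq",
    "strelka",
)
DEFAULT_INDEL_CALLERS: tuple[str, ...] = DEFAULT_SNV_CALLERS + ("scalpel",)


class ConsensusConfigError(ValueError):
    """A call references a caller outside the configured caller sets."""


@dataclass(frozen=True)
class ConsensusConfig:
    snv_caller_set: tuple[str, ...] = DEFAULT_SNV_CALLERS
    indel_caller_set: tuple[str, ...] = DEFAULT_INDEL_CALLERS
    min_support_snv: int = 3
    min_support_indel: int = 3
    count_nonpass_calls: bool = False
    vaf_aggregation: str = "median"  # or "primary_caller"
    primary_caller: str | None = None

    def __post_init__(self) -> None:
        if not 1 <= self.min_support_snv <= len(self.snv_caller_set):
            raise ValueError("min_support_snv outside [1, |snv_caller_set|]")
        if not 1 <= self.min_support_indel <= len(self.indel_caller_set):
            raise ValueError("min_support_indel outside [1, |indel_caller_set|]")
        if self.vaf_aggregation not in {"median", "primary_caller"}:
            raise ValueError(f"unknown vaf_aggregation {self.vaf_aggregation!r}")
        if self.vaf_aggregation == "primary_caller" and not self.primary_caller:
            raise ValueError("primary_caller mode requires a primary_caller id")

    def caller_set_for(self, variant_class: VariantClass) -> tuple[str, ...]:
        if variant_class is VariantClass.SNV:
            return self.snv_caller_set
        return self.indel_caller_set

    def min_support_for(self, variant_class: VariantClass) -> int:
        if variant_class is VariantClass.SNV:
            return self.min_support_snv
        return self.min_support_indel


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def aggregate_vaf(
    supporting_calls: Sequence[CallerCall], config: ConsensusConfig | None = None
) -> tuple[float, int, int]:
    """Aggregate (vaf, alt_depth, total_depth) across supporting callers.

    Default: per-field median (even counts take the mean of the two middle
    values; depths are rounded half-up back to integers). In
    ``primary_caller`` mode the designated caller's fields are returned
    verbatim and its absence from the support set is an error.
    """
    if not supporting_calls:
        raise ValueError("empty support set")
    config = config or ConsensusConfig()
    if config.vaf_aggregation == "primary_caller":
        for call in supporting_calls:
            if call.caller_id == config.primary_caller:
                return call.vaf, call.alt_depth, call.total_depth
        raise ConsensusConfigError(
            f"primary caller {config.primary_caller!r} is not a supporter"
        )
    vaf = float(np.median([c.vaf for c in supporting_calls]))
    alt_depth = _round_half_up(float(np.median([c.alt_depth for c in supporting_calls])))
    total_depth = _round_half_up(float(np.median([c.total_depth for c in supporting_calls])))
    return vaf, alt_depth, max(total_depth, alt_depth)


def merge_callers(
    per_caller_calls: Iterable[CallerCall],
    config: ConsensusConfig | None = None,
    sample_id: str = "",
) -> list[ConsensusVariant]:
    """Merge per-caller call sets into consensus variants.

    A normalized variant is retained iff it is supported by at least the
    configured minimum number of callers of its class (SNV vs indel).
    Output order is deterministic: (chrom, pos, ref, alt).
    """
    config = config or ConsensusConfig()
    known = set(config.snv_caller_set) | set(config.indel_caller_set)

    by_variant: dict[GenomicVariant, list[CallerCall]] = defaultdict(list)
    for call in per_caller_calls:
        if call.caller_id not in known:
            raise ConsensusConfigError(f"caller {call.caller_id!r} not in configured sets")
        by_variant[call.variant].append(call)

    merged: list[ConsensusVariant] = []
    for variant in sorted(by_variant, key=lambda v: v.key):
        calls = by_variant[variant]
        caller_set = set(config.caller_set_for(variant.variant_class))
        supporters: dict[str, CallerCall] = {}
        for call in calls:
            if call.caller_id not in caller_set:
                continue
            if not call.passed_caller_filter and not config.count_nonpass_calls:
                continue
            supporters.setdefault(call.caller_id, call)
        if len(supporters) < config.min_support_for(variant.variant_class):
            continue
        vaf, alt_depth, total_depth = aggregate_vaf(list(supporters.values()), config)
        merged.append(
            ConsensusVariant(
                variant=variant,
                supporting_callers=frozenset(supporters),
                vaf=vaf,
                alt_depth=alt_depth,
                total_depth=total_depth,
                sample_id=sample_id,
            )
        )
    return merged
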