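"""Annotation evidence attached to a normalized variant.

The toolkit consumes annotation as a table produced upstream (gene model,
population allele frequencies across databases and subpopulations, dbSNP /
COSMIC / ClinVar identifiers, and presence in a local population database).
Absent frequencies are represented as missing, never as zero: "not observed
in gnomAD" and "observed at AF 0" carry different evidence for the
somatic/germline call.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Mapping, Optional

__all__ = ["Consequence", "PROTEIN_AFFECTING", "AnnotationRecord"]

from .variants import GenomicVariant

#: Controlled vocabulary for functional consequence.
Consequence = str

CONSEQUENCES = (
    "missense",
    "nonsense",
    "frameshift_del",
    "frameshift_ins",
    "inframe_del",
    "inframe_ins",
    "splice_site",
    "synonymous",
    "other",
)

#: Consequences counted as protein-affecting (eligible for gene-level
#: biomarker rules and for the non-synonymous cohort summaries).
PROTEIN_AFFECTING = frozenset(CONSEQUENCES) - {"synonymous", "other"}


@dataclass(frozen=True)
class AnnotationRecord:
    """Database evidence for one normalized variant.

    ``pop_afs`` maps ``(database, subpopulation)`` to an allele frequency in
    [0, 1]; a pair that is absent from the map was absent from the database.
    ``local_db_af`` is the frequency in the local (e.g. Chilean) germline
    database, used both in the population-frequency maximum and as germline
    evidence in classification.
    """

    variant: GenomicVariant
    gene: str
    consequence: Consequence = "other"
    protein_change: str = ""
    pop_afs: Mapping[tuple[str, str], float] = field(default_factory=dict)
    dbsnp_id: Optional[str] = None
    cosmic_id: Optional[str] = None
    cosmic_count: int = 0
    clinvar_sig: Optional[str] = None
    local_db_af: Optional[float] = None

    def __post_init__(self) -> None:
        if self.consequence not in CONSEQUENCES:
            raise ValueError(f"unknown consequence {self.consequence!r}")
        for key, af in self.pop_afs.items():
            if not 0.0 <= af <= 1.0:
                raise ValueError(f"population AF {af} for {key} outside [0, 1]")
        if self.local_db_af is not None and not 0.0 <= self.local_db_af <= 1.0:
            raise ValueError(f"local_db_af {self.local_db_af} outside [0, 1]")
        if self.cosmic_id is not None and self.cosmic_count < 1:
            raise ValueError("cosmic_id present implies cosmic_count >= 1")
        # freeze the mapping so records are safely hashable by identity-free use
        object.__setattr__(self, "pop_afs", MappingProxyType(dict(self.pop_afs)))

    @property
    def has_pvd_entry(self) -> bool:
        """Any population variant database (gnomAD/ExAC/1000G/ESP6500) entry."""
        return len(self.pop_afs) > 0

    @property
    def is_protein_affecting(self) -> bool:
        return self.consequence in PROTEIN_AFFECTING
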