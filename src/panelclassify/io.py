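"""Readers and writers for the formats the toolkit touches.

VCF 4.2 input is parsed with cyvcf2; BED is 0-based half-open; the
annotation table and all report tables are TSV handled through pandas.
All genomic positions are 1-based internally (the BED reader converts).
VCF output is emitted by a small template writer whose product is
round-trip checked through cyvcf2.
"""

from __future__ import annotations

import csv
import warnings
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .annotations import AnnotationRecord
from .classify import Category, ClassifiedVariant
from .variants import (
    CallerCall,
    ConsensusVariant,
    GenomicVariant,
    TargetRegion,
    VariantError,
    merge_regions,
    normalize_variant,
)

__all__ = [
    "DEFAULT_TAG_MAP",
    "read_caller_vcf",
    "write_caller_vcf",
    "read_targets_bed",
    "read_annotation_table",
    "write_annotation_table",
    "write_variants",
    "read_consensus_vcf",
    "read_consensus_tsv",
    "read_classified_tsv",
]

#: FORMAT/INFO keys holding VAF and depths, caller by caller convention.
DEFAULT_TAG_MAP: Mapping[str, str] = {"vaf": "AF", "alt_depth": "AD", "total_depth": "DP"}

_ANNOTATION_FIXED_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "gene",
    "consequence",
    "protein_change",
    "dbsnp_id",
    "cosmic_id",
    "cosmic_count",
    "clinvar_sig",
    "local_db_af",
]


# ---------------------------------------------------------------------------
# VCF input
# ---------------------------------------------------------------------------


def _format_scalar(record, key: str, allele_index: int):
    """Fetch a FORMAT value (first sample) or fall back to INFO."""
    try:
        arr = record.format(key)
    except KeyError:
        arr = None
    if arr is not None:
        row = np.asarray(arr)[0].ravel()
        row = row[~np.isnan(row.astype(float))] if row.dtype.kind == "f" else row
        if len(row) == 0:
            return None
        # per-allele fields (e.g. AF for multi-allelic records)
        idx = allele_index if len(row) > allele_index else 0
        return row[idx]
    value = record.INFO.get(key)
    if value is None:
        return None
    if isinstance(value, (tuple, list)):
        return value[allele_index] if len(value) > allele_index else value[0]
    return value


def read_caller_vcf(
    path: str | Path,
    caller_id: str,
    tag_map: Mapping[str, str] | None = None,
) -> list[CallerCall]:
    """Read one caller's VCF into normalized :class:`CallerCall` records.

    Multi-allelic records are split into one call per ALT allele, with
    per-allele alt depths taken from the ordered AD field. Records failing
    the caller's own FILTER column are retained with
    ``passed_caller_filter=False``. When the VAF tag is absent the VAF is
    recomputed as alt_depth / total_depth. Records whose depths cannot be
    determined are skipped with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    tags = dict(DEFAULT_TAG_MAP, **(tag_map or {}))

    calls: list[CallerCall] = []
    n_skipped = 0
    for record in VCF(str(path)):
        passed = record.FILTER in (None, "PASS", ".")
        ad = None
        try:
            raw_ad = record.format(tags["alt_depth"])
        except KeyError:
            raw_ad = None
        if raw_ad is not None:
            ad = np.asarray(raw_ad)[0].ravel()

        for i, alt in enumerate(record.ALT):
            if not alt or not set(alt) <= set("ACGTNacgtn"):
                n_skipped += 1
                continue
            try:
                variant = normalize_variant(record.CHROM, record.POS, record.REF, alt)
            except VariantError:
                n_skipped += 1
                continue

            alt_depth = None
            if ad is not None and len(ad) > i + 1 and int(ad[i + 1]) >= 0:
                alt_depth = int(ad[i + 1])
            total = _format_scalar(record, tags["total_depth"], i)
            total_depth = int(total) if total is not None and int(total) >= 0 else None
            if total_depth is None and ad is not None:
                nonneg = ad[ad >= 0]
                total_depth = int(nonneg.sum()) if len(nonneg) else None
            if alt_depth is None or total_depth is None:
                n_skipped += 1
                continue
            total_depth = max(total_depth, alt_depth)

            vaf = _format_scalar(record, tags["vaf"], i)
            if vaf is None:
                vaf = alt_depth / total_depth if total_depth > 0 else 0.0
            else:
                # htslib stores Float fields in single precision; round to the
                # 6 significant digits the writers emit so values round-trip
                vaf = float(f"{float(vaf):.6g}")
            calls.append(
                CallerCall(
                    variant=variant,
                    caller_id=caller_id,
                    vaf=float(vaf),
                    alt_depth=alt_depth,
                    total_depth=total_depth,
                    passed_caller_filter=passed,
                )
            )
    if n_skipped:
        warnings.warn(
            f"{path.name}: skipped {n_skipped} record(s) without usable depths/alleles",
            stacklevel=2,
        )
    return calls


def _vcf_header(contigs: Sequence[str], sample_id: str | None, info_lines: Sequence[str]) -> str:
    lines = ["##fileformat=VCFv4.2", "##source=panelclassify"]
    lines += [f"##contig=<ID={c}>" for c in contigs]
    lines += list(info_lines)
    columns = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO"]
    if sample_id is not None:
        columns += ["FORMAT", sample_id]
    return "\n".join(lines + ["\t".join(columns)]) + "\n"


def write_caller_vcf(
    calls: Sequence[CallerCall], path: str | Path, sample_id: str = "TUMOR"
) -> None:
    """Write caller-style calls as a single-sample VCF with GT/AD/DP/AF."""
    contigs = sorted({c.variant.chrom for c in calls})
    info_lines = [
        '##FILTER=<ID=caller_filtered,Description="Failed the caller internal filter">',
        '##INFO=<ID=AF,Number=A,Type=Float,Description="Variant allele fraction">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Total depth">',
        '##FORMAT=<ID=AF,Number=A,Type=Float,Description="Variant allele fraction">',
    ]
    rows = []
    for call in sorted(calls, key=lambda c: c.variant.key):
        v = call.variant
        filt = "PASS" if call.passed_caller_filter else "caller_filtered"
        sample = (
            f"0/1:{call.total_depth - call.alt_depth},{call.alt_depth}"
            f":{call.total_depth}:{call.vaf:.6g}"
        )
        rows.append(
            f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\t{filt}\tAF={call.vaf:.6g}"
            f"\tGT:AD:DP:AF\t{sample}"
        )
    Path(path).write_text(_vcf_header(contigs, sample_id, info_lines) + "".join(r + "\n" for r in rows))


# ---------------------------------------------------------------------------
# BED targets
# ---------------------------------------------------------------------------


def read_targets_bed(path: str | Path) -> list[TargetRegion]:
    """Read a BED3+ file; regions are sorted and merged per chromosome."""
    regions: list[TargetRegion] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 BED columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start {start} >= end {end}")
            name = fields[3] if len(fields) > 3 else ""
            regions.append(TargetRegion(chrom, start, end, name))
    return merge_regions(regions)


# ---------------------------------------------------------------------------
# Annotation table
# ---------------------------------------------------------------------------


def _split_af_column(name: str) -> Optional[tuple[str, str]]:
    """``gnomad_genome_AMR`` → ``("gnomad_genome", "AMR")``; None if not an
    AF-shaped column (database prefix + upper-case subpopulation suffix)."""
    if "_" not in name:
        return None
    db, _, subpop = name.rpartition("_")
    if db and subpop and subpop.isupper():
        return db, subpop
    return None


def read_annotation_table(path: str | Path) -> list[AnnotationRecord]:
    """Read the annotation TSV into one record per normalized variant.

    Absent frequencies (empty cells) are distinguished from zero: they are
    simply missing from ``pop_afs``. Unknown non-AF columns are ignored
    with a warning; duplicate variant keys are an error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _ANNOTATION_FIXED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing annotation columns {missing}")
    af_columns: dict[str, tuple[str, str]] = {}
    for col in df.columns:
        if col in _ANNOTATION_FIXED_COLUMNS:
            continue
        key = _split_af_column(col)
        if key is None:
            warnings.warn(f"{path}: ignoring unknown column {col!r}", stacklevel=2)
        else:
            af_columns[col] = key

    records: list[AnnotationRecord] = []
    seen: set[tuple] = set()
    for _, row in df.iterrows():
        variant = normalize_variant(row["chrom"], int(row["pos"]), row["ref"], row["alt"])
        if variant.key in seen:
            raise ValueError(f"{path}: duplicate variant key {variant}")
        seen.add(variant.key)
        pop_afs = {
            key: float(row[col]) for col, key in af_columns.items() if row[col] != ""
        }
        records.append(
            AnnotationRecord(
                variant=variant,
                gene=row["gene"],
                consequence=row["consequence"] or "other",
                protein_change=row["protein_change"],
                pop_afs=pop_afs,
                dbsnp_id=row["dbsnp_id"] or None,
                cosmic_id=row["cosmic_id"] or None,
                cosmic_count=int(row["cosmic_count"] or 0),
                clinvar_sig=row["clinvar_sig"] or None,
                local_db_af=float(row["local_db_af"]) if row["local_db_af"] != "" else None,
            )
        )
    return records


def write_annotation_table(records: Sequence[AnnotationRecord], path: str | Path) -> None:
    """Write annotation records to TSV (inverse of :func:`read_annotation_table`)."""
    af_keys = sorted({key for r in records for key in r.pop_afs})
    af_cols = [f"{db}_{sub}" for db, sub in af_keys]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_ANNOTATION_FIXED_COLUMNS + af_cols)
        for r in sorted(records, key=lambda r: r.variant.key):
            v = r.variant
            row = [
                v.chrom,
                v.pos,
                v.ref,
                v.alt,
                r.gene,
                r.consequence,
                r.protein_change,
                r.dbsnp_id or "",
                r.cosmic_id or "",
                r.cosmic_count,
                r.clinvar_sig or "",
                repr(r.local_db_af) if r.local_db_af is not None else "",
            ]
            row += [repr(r.pop_afs[key]) if key in r.pop_afs else "" for key in af_keys]
            writer.writerow(row)


# ---------------------------------------------------------------------------
# Consensus / classified variant output
# ---------------------------------------------------------------------------

_CONSENSUS_COLUMNS = [
    "sample_id",
    "chrom",
    "pos",
    "ref",
    "alt",
    "variant_class",
    "supporting_callers",
    "n_support",
    "vaf",
    "alt_depth",
    "total_depth",
]

_CLASSIFIED_EXTRA = [
    "category",
    "rule_trail",
    "gene",
    "consequence",
    "protein_change",
    "dbsnp_id",
    "cosmic_id",
    "cosmic_count",
    "clinvar_sig",
    "local_db_af",
    "pop_afs",
]


def _consensus_row(v: ConsensusVariant) -> list:
    return [
        v.sample_id,
        v.variant.chrom,
        v.variant.pos,
        v.variant.ref,
        v.variant.alt,
        v.variant_class.value,
        ",".join(sorted(v.supporting_callers)),
        v.n_support,
        repr(v.vaf),
        v.alt_depth,
        v.total_depth,
    ]


def _encode_pop_afs(ann: AnnotationRecord) -> str:
    return ";".join(
        f"{db}_{sub}={repr(af)}" for (db, sub), af in sorted(ann.pop_afs.items())
    )


def _decode_pop_afs(text: str) -> dict[tuple[str, str], float]:
    out: dict[tuple[str, str], float] = {}
    for chunk in filter(None, text.split(";")):
        name, _, value = chunk.partition("=")
        key = _split_af_column(name)
        if key is None:
            raise ValueError(f"bad population-AF token {chunk!r}")
        out[key] = float(value)
    return out


def write_variants(
    records: Sequence[ConsensusVariant] | Sequence[ClassifiedVariant],
    path: str | Path,
    format: str = "tsv",
) -> None:
    """Write consensus or classified variants as TSV or VCF.

    Field order is deterministic (sorted by sample then genomic key) and the
    TSV round-trips through :func:`read_consensus_tsv` /
    :func:`read_classified_tsv`; consensus VCF round-trips through
    :func:`read_consensus_vcf`.
    """
    if format not in {"tsv", "vcf"}:
        raise ValueError(f"unsupported format {format!r}")
    classified = bool(records) and isinstance(records[0], ClassifiedVariant)

    if format == "tsv":
        columns = _CONSENSUS_COLUMNS + (_CLASSIFIED_EXTRA if classified else [])
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(columns)
            key = (
                (lambda r: (r.sample_id, r.consensus.variant.key))
                if classified
                else (lambda r: (r.sample_id, r.variant.key))
            )
            for record in sorted(records, key=key):
                if classified:
                    ann = record.annotation
                    row = _consensus_row(record.consensus) + [
                        record.category.value,
                        ",".join(record.rule_trail),
                        ann.gene,
                        ann.consequence,
                        ann.protein_change,
                        ann.dbsnp_id or "",
                        ann.cosmic_id or "",
                        ann.cosmic_count,
                        ann.clinvar_sig or "",
                        repr(ann.local_db_af) if ann.local_db_af is not None else "",
                        _encode_pop_afs(ann),
                    ]
                else:
                    row = _consensus_row(record)
                writer.writerow(row)
        return

    # VCF output
    consensus_of = (lambda r: r.consensus) if classified else (lambda r: r)
    contigs = sorted({consensus_of(r).variant.chrom for r in records})
    info_lines = [
        '##INFO=<ID=NSUP,Number=1,Type=Integer,Description="Number of supporting callers">',
        '##INFO=<ID=CALLERS,Number=.,Type=String,Description="Supporting caller ids">',
        '##INFO=<ID=VAF,Number=1,Type=Float,Description="Aggregated variant allele fraction">',
        '##INFO=<ID=ADP,Number=1,Type=Integer,Description="Aggregated alt depth">',
        '##INFO=<ID=DP,Number=1,Type=Integer,Description="Aggregated total depth">',
        '##INFO=<ID=SAMPLE,Number=1,Type=String,Description="Sample id">',
        '##INFO=<ID=CATEGORY,Number=1,Type=String,Description="Origin category">',
    ]
    lines = [_vcf_header(contigs, None, info_lines)]
    for record in sorted(records, key=lambda r: (consensus_of(r).sample_id, consensus_of(r).variant.key)):
        v = consensus_of(record)
        info = (
            f"NSUP={v.n_support};CALLERS={','.join(sorted(v.supporting_callers))}"
            f";VAF={v.vaf:.6g};ADP={v.alt_depth};DP={v.total_depth}"
        )
        if v.sample_id:
            info += f";SAMPLE={v.sample_id}"
        if classified:
            info += f";CATEGORY={record.category.value}"
        g = v.variant
        lines.append(f"{g.chrom}\t{g.pos}\t.\t{g.ref}\t{g.alt}\t.\tPASS\t{info}\n")
    Path(path).write_text("".join(lines))


def read_consensus_vcf(path: str | Path) -> list[ConsensusVariant]:
    """Inverse of ``write_variants(..., format="vcf")`` for consensus records."""
    out: list[ConsensusVariant] = []
    for record in VCF(str(path)):
        for alt in record.ALT:
            variant = normalize_variant(record.CHROM, record.POS, record.REF, alt)
            callers = record.INFO.get("CALLERS") or ""
            out.append(
                ConsensusVariant(
                    variant=variant,
                    supporting_callers=frozenset(filter(None, str(callers).split(","))),
                    vaf=float(f"{float(record.INFO.get('VAF')):.6g}"),
                    alt_depth=int(record.INFO.get("ADP")),
                    total_depth=int(record.INFO.get("DP")),
                    sample_id=str(record.INFO.get("SAMPLE") or ""),
                )
            )
    return out


def _consensus_from_row(row: Mapping[str, str]) -> ConsensusVariant:
    return ConsensusVariant(
        variant=GenomicVariant(row["chrom"], int(row["pos"]), row["ref"], row["alt"]),
        supporting_callers=frozenset(filter(None, row["supporting_callers"].split(","))),
        vaf=float(row["vaf"]),
        alt_depth=int(row["alt_depth"]),
        total_depth=int(row["total_depth"]),
        sample_id=row["sample_id"],
    )


def read_consensus_tsv(path: str | Path) -> list[ConsensusVariant]:
    with open(path, newline="") as fh:
        return [_consensus_from_row(row) for row in csv.DictReader(fh, delimiter="\t")]


def read_classified_tsv(path: str | Path) -> list[ClassifiedVariant]:
    """Inverse of ``write_variants`` for classified-variant TSVs."""
    out: list[ClassifiedVariant] = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            consensus = _consensus_from_row(row)
            annotation = AnnotationRecord(
                variant=consensus.variant,
                gene=row["gene"],
                consequence=row["consequence"],
                protein_change=row["protein_change"],
                pop_afs=_decode_pop_afs(row["pop_afs"]),
                dbsnp_id=row["dbsnp_id"] or None,
                cosmic_id=row["cosmic_id"] or None,
                cosmic_count=int(row["cosmic_count"] or 0),
                clinvar_sig=row["clinvar_sig"] or None,
                local_db_af=float(row["local_db_af"]) if row["local_db_af"] else None,
            )
            out.append(
                ClassifiedVariant(
                    consensus=consensus,
                    annotation=annotation,
                    category=Category(row["category"]),
                    rule_trail=tuple(filter(None, row["rule_trail"].split(","))),
                )
            )
    return out
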