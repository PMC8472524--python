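"""End-to-end orchestration: QC -> consensus -> filter/classify -> report.

The pipeline consumes a cohort directory with the layout the simulator
emits (and which mirrors what an upstream alignment/calling stack would
produce):

    samples.tsv                sample_id <tab> tumor_type
    targets.bed                panel target regions
    annotations.tsv            annotation table for all variants
    vcf/<sample>.<caller>.vcf  one VCF per sample and caller
    depths/<sample>.regions.tsv  per-region mean depths

QC gating is per sample: a sample failing the coverage rule is reported in
the QC table but its variants are not classified, and the cohort run
continues. All outputs are deterministic for fixed inputs; the manifest
lists every produced file with a SHA-256 checksum.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Optional

import pandas as pd

from . import biomarkers, qc
from .classify import ClassifiedVariant, run_filters_and_classify
from .config import RunConfig
from .io import read_annotation_table, read_caller_vcf, read_targets_bed, write_variants
from .consensus import merge_callers

logger = logging.getLogger("panelclassify")

__all__ = ["PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """Fatal pipeline problem (missing inputs, invalid configuration)."""


def _require(path: Path, what: str) -> Path:
    if not path.exists():
        raise PipelineError(f"missing {what}: {path}")
    return path


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(
    cohort_dir: str | Path,
    out_dir: str | Path,
    config: Optional[RunConfig] = None,
) -> Path:
    """Run the full per-sample pipeline over a cohort directory.

    Returns the output directory; raises :class:`PipelineError` on the
    first fatal problem (before any computation for configuration issues).
    """
    config = config or RunConfig()
    cohort = Path(cohort_dir)
    out = Path(out_dir)

    samples_path = _require(cohort / "samples.tsv", "sample metadata")
    _require(cohort / "targets.bed", "target BED")
    annotations_path = _require(cohort / "annotations.tsv", "annotation table")
    kb_path = None
    if config.kb_path is not None:
        kb_path = _require(Path(config.kb_path), "knowledge base")

    out.mkdir(parents=True, exist_ok=True)
    meta = pd.read_csv(samples_path, sep="\t", dtype=str)
    read_targets_bed(cohort / "targets.bed")  # validated even though QC uses depth tables
    annotations = {a.variant.key: a for a in read_annotation_table(annotations_path)}
    consensus_cfg = config.consensus.build()
    filter_cfg = config.filters.build()

    qc_summaries = []
    all_classified: list[ClassifiedVariant] = []
    dropped_rows = []
    for sample in meta["sample_id"]:
        depth_path = _require(
            cohort / "depths" / f"{sample}.regions.tsv", f"depth table for {sample}"
        )
        region_depths = qc.read_region_depths(depth_path)["mean_depth"].tolist()
        summary = qc.summarize_sample(
            sample,
            region_depths,
            thresholds=config.qc.thresholds,
            uniformity_factor=config.qc.uniformity_factor,
        )
        qc_summaries.append(summary)
        if not qc.sample_pass(summary, config.qc.mode):
            logger.warning("sample %s failed %s QC; skipping classification", sample, config.qc.mode)
            continue

        calls = []
        for caller in dict.fromkeys(consensus_cfg.snv_caller_set + consensus_cfg.indel_caller_set):
            vcf_path = cohort / "vcf" / f"{sample}.{caller}.vcf"
            if vcf_path.exists():
                calls.extend(read_caller_vcf(vcf_path, caller))
        consensus = merge_callers(calls, consensus_cfg, sample_id=sample)
        classified, dropped = run_filters_and_classify(consensus, annotations, filter_cfg)
        all_classified.extend(classified)
        dropped_rows += [
            {
                "sample_id": sample,
                "chrom": v.variant.chrom,
                "pos": v.variant.pos,
                "ref": v.variant.ref,
                "alt": v.variant.alt,
                "reasons": ",".join(reasons),
            }
            for v, reasons in dropped
        ]

    qc.qc_report(qc_summaries, out / "qc_report.tsv")
    write_variants(all_classified, out / "classified.tsv", format="tsv")
    pd.DataFrame(
        dropped_rows, columns=["sample_id", "chrom", "pos", "ref", "alt", "reasons"]
    ).to_csv(out / "dropped.tsv", sep="\t", index=False)
    biomarkers.summarize_classification(all_classified).to_csv(
        out / "category_counts.tsv", sep="\t", index=False
    )

    sample_meta = dict(zip(meta["sample_id"], meta["tumor_type"]))
    matrix = biomarkers.gene_tumor_matrix(all_classified, sample_meta)
    if not matrix.matrix.empty:
        matrix.matrix.to_csv(out / "gene_tumor_matrix.tsv", sep="\t")

    if kb_path is not None:
        kb = biomarkers.load_knowledge_base(kb_path)
        hits = biomarkers.match_biomarkers(all_classified, kb)
        pd.DataFrame(
            [
                {
                    "sample_id": h.sample_id,
                    "chrom": h.variant_key[0],
                    "pos": h.variant_key[1],
                    "ref": h.variant_key[2],
                    "alt": h.variant_key[3],
                    "gene": h.gene,
                    "protein_change": h.protein_change,
                    "drug": h.drug,
                    "effect": h.effect,
                    "evidence_tier": h.evidence_tier.label,
                    "matched_by": h.matched_by,
                }
            for h in hits
            ],
            columns=[
                "sample_id", "chrom", "pos", "ref", "alt", "gene",
                "protein_change", "drug", "effect", "evidence_tier", "matched_by",
            ],
        ).to_csv(out / "biomarker_hits.tsv", sep="\t", index=False)

    manifest = {
        "outputs": {
            p.name: _checksum(p)
            for p in sorted(out.iterdir())
            if p.is_file() and p.name != "manifest.json"
        }
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return out
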