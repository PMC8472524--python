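import pytest

from panelclassify.annotations import AnnotationRecord
from panelclassify.variants import CallerCall, ConsensusVariant, GenomicVariant


def make_variant(chrom="chr1", pos=100, ref="A", alt="C") -> GenomicVariant:
    return GenomicVariant(chrom, pos, ref, alt)


def make_call(
    caller_id="mutect2",
    chrom="chr1",
    pos=100,
    ref="A",
    alt="C",
    vaf=0.10,
    alt_depth=50,
    total_depth=500,
    passed=True,
) -> CallerCall:
    return CallerCall(
        variant=GenomicVariant(chrom, pos, ref, alt),
        caller_id=caller_id,
        vaf=vaf,
        alt_depth=alt_depth,
        total_depth=total_depth,
        passed_caller_filter=passed,
    )


def make_consensus(
    chrom="chr1",
    pos=100,
    ref="A",
    alt="C",
    vaf=0.10,
    alt_depth=50,
    total_depth=500,
    callers=("mutect2", "varscan2", "lofreq"),
    sample_id="S1",
) -> ConsensusVariant:
    return ConsensusVariant(
        variant=GenomicVariant(chrom, pos, ref, alt),
        supporting_callers=frozenset(callers),
        vaf=vaf,
        alt_depth=alt_depth,
        total_depth=total_depth,
        sample_id=sample_id,
    )


def make_annotation(variant=None, gene="TP53", **kwargs) -> AnnotationRecord:
    variant = variant or make_variant()
    kwargs.setdefault("consequence", "missense")
    kwargs.setdefault("protein_change", "R175H")
    return AnnotationRecord(variant=variant, gene=gene, **kwargs)


@pytest.fixture
def small_cohort(tmp_path):
    """A small deterministic synthetic cohort written to disk."""
    from panelclassify.simulate import CohortConfig, generate_cohort

    cohort = generate_cohort(CohortConfig(seed=11, n_samples=3))
    cohort_dir = cohort.write(tmp_path / "cohort")
    return cohort, cohort_dir
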