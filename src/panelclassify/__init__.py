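"""panelclassify: tumor-only targeted-panel variant toolkit.

Multi-caller consensus somatic calling, detection-limit and
population-frequency filtering with subpopulation awareness, six-category
somatic/germline classification for tumor-only data, panel coverage QC,
and actionable-biomarker matching with tiered drug evidence.
"""

from importlib.resources import files as _files

from .annotations import AnnotationRecord
from .biomarkers import (
    BiomarkerHit,
    BiomarkerRule,
    EvidenceTier,
    load_knowledge_base,
    match_biomarkers,
    percent,
    set_concordance,
    summarize_classification,
    gene_tumor_matrix,
    vaf_concordance,
)
from .classify import (
    Category,
    ClassifiedVariant,
    FilterConfig,
    GERMLINE_FAMILY,
    SOMATIC_FAMILY,
    apply_detection_filters,
    apply_germline_hard_filters,
    apply_population_filter,
    classify_variant,
    max_population_af,
    run_filters_and_classify,
)
from .consensus import ConsensusConfig, aggregate_vaf, merge_callers
from .config import RunConfig, load_config
from .pipeline import run_pipeline
from .qc import QCSummary, qc_report, region_coverage_fractions, sample_pass, uniformity
from .simulate import (
    Cohort,
    CohortConfig,
    TruthVariant,
    generate_cohort,
    hd_like_truth_set,
    recovery_metrics,
)
from .variants import (
    CallerCall,
    ConsensusVariant,
    GenomicVariant,
    TargetRegion,
    normalize_variant,
)

__version__ = "0.1.0"


def fixture_path(name: str):
    """Path to a packaged fixture TSV (knowledge bases, cohort count tables)."""
    return _files("panelclassify") / "data" / name
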