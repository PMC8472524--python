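"""Detection/population filters, six-category rules, germline hard filters."""

import numpy as np
import pytest

from conftest import make_annotation, make_consensus, make_variant
from panelclassify.classify import (
    Category,
    ClassificationError,
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

CFG = FilterConfig()


class TestDetectionFilters:
    @pytest.mark.parametrize(
        "vaf, alt_depth, keep, reasons",
        [
            (0.05, 12, True, ()),  # both boundaries inclusive
            (0.04, 30, False, ("low_vaf",)),
            (0.20, 11, False, ("low_alt_depth",)),
            (0.01, 3, False, ("low_vaf", "low_alt_depth")),
        ],
    )
    def test_boundaries_and_reasons(self, vaf, alt_depth, keep, reasons):
        v = make_consensus(vaf=vaf, alt_depth=alt_depth)
        decision = apply_detection_filters(v, CFG)
        assert decision.keep is keep
        assert decision.reasons == reasons


class TestPopulationFilter:
    def test_max_over_subpopulations(self):
        ann = make_annotation(
            pop_afs={("gnomad_genome", "ALL"): 0.002, ("gnomad_genome", "AMR"): 0.015}
        )
        assert max_population_af(ann) == 0.015

    def test_absent_everywhere(self):
        assert max_population_af(make_annotation()) is None

    def test_local_db_participates(self):
        ann = make_annotation(pop_afs={("g1000", "ALL"): 0.009}, local_db_af=0.03)
        assert max_population_af(ann) == 0.03
        assert max_population_af(ann, include_local=False) == 0.009

    @pytest.mark.parametrize(
        "max_af, keep",
        [(0.02, False), (0.0101, False), (0.01, True), (0.009, True), (None, True)],
    )
    def test_strict_inequality(self, max_af, keep):
        pop_afs = {("gnomad_genome", "ALL"): max_af} if max_af is not None else {}
        decision = apply_population_filter(
            make_consensus(), make_annotation(pop_afs=pop_afs), CFG
        )
        assert decision.keep is keep
        if not keep:
            assert decision.reasons == ("common_polymorphism",)


class TestClassification:
    def test_cosmic_only_is_somatic(self):
        v = make_consensus(vaf=0.12)
        ann = make_annotation(v.variant, cosmic_id="COSV1", cosmic_count=12)
        cv = classify_variant(v, ann, CFG)
        assert cv.category is Category.SOMATIC
        assert cv.rule_trail[-1] == "R2_fired"

    def test_novel_in_band_is_putative_novel_germline(self):
        v = make_consensus(vaf=0.48)
        cv = classify_variant(v, make_annotation(v.variant), CFG)
        assert cv.category is Category.PUTATIVE_NOVEL_GERMLINE
        assert cv.rule_trail[-1] == "R6_fired"

    def test_dbsnp_rare_offband_is_putative_somatic(self):
        v = make_consensus(vaf=0.23)
        ann = make_annotation(
            v.variant, dbsnp_id="rs1", pop_afs={("gnomad_genome", "AMR"): 0.004}
        )
        cv = classify_variant(v, ann, CFG)
        assert cv.category is Category.PUTATIVE_SOMATIC
        assert cv.rule_trail[-1] == "R5_fired"

    @pytest.mark.parametrize(
        "kwargs", [{"clinvar_sig": "pathogenic_germline"}, {"local_db_af": 0.005}]
    )
    def test_germline_evidence_wins_first(self, kwargs):
        v = make_consensus(vaf=0.12)  # VAF irrelevant for R1
        ann = make_annotation(v.variant, cosmic_id="COSV9", cosmic_count=30, **kwargs)
        assert classify_variant(v, ann, CFG).category is Category.GERMLINE

    def test_cosmic_with_dbsnp_offband_is_putative_somatic(self):
        v = make_consensus(vaf=0.25)
        ann = make_annotation(v.variant, cosmic_id="COSV2", cosmic_count=3, dbsnp_id="rs2")
        cv = classify_variant(v, ann, CFG)
        assert cv.category is Category.PUTATIVE_SOMATIC
        assert cv.rule_trail[-1] == "R3_fired"

    def test_dbsnp_in_band_is_putative_germline(self):
        v = make_consensus(vaf=0.55)
        ann = make_annotation(v.variant, dbsnp_id="rs3")
        assert classify_variant(v, ann, CFG).category is Category.PUTATIVE_GERMLINE

    def test_novel_offband_is_putative_novel_somatic(self):
        v = make_consensus(vaf=0.70)  # between the het and hom bands
        assert (
            classify_variant(v, make_annotation(v.variant), CFG).category
            is Category.PUTATIVE_NOVEL_SOMATIC
        )

    def test_missing_annotation_is_an_error(self):
        with pytest.raises(ClassificationError, match="chr1:100"):
            classify_variant(make_consensus(), None, CFG)

    def test_golden_default_rule_order(self):
        """Frozen assignments for a crafted record panel under the default
        rule order; permuting R4/R5 flips the in-band dbSNP record."""
        v_band = make_consensus(vaf=0.50)
        v_off = make_consensus(vaf=0.20)
        panel = [
            (v_band, make_annotation(v_band.variant, dbsnp_id="rs9"), Category.PUTATIVE_GERMLINE),
            (v_off, make_annotation(v_off.variant, dbsnp_id="rs9"), Category.PUTATIVE_SOMATIC),
            (
                v_band,
                make_annotation(v_band.variant, cosmic_id="C1", cosmic_count=5, dbsnp_id="rs9"),
                Category.PUTATIVE_GERMLINE,
            ),
            (v_band, make_annotation(v_band.variant), Category.PUTATIVE_NOVEL_GERMLINE),
        ]
        for v, ann, expected in panel:
            assert classify_variant(v, ann, CFG).category is expected

        swapped = FilterConfig(rule_order=("R1", "R2", "R3", "R5", "R4", "R6"))
        v, ann, _ = panel[0]
        assert classify_variant(v, ann, swapped).category is Category.PUTATIVE_SOMATIC

    def test_category_partition_on_random_records(self):
        """Every record gets exactly one category; family counts sum to n."""
        rng = np.random.default_rng(0)
        n = 200
        categories = []
        for i in range(n):
            vaf = float(rng.uniform(0.05, 1.0))
            v = make_consensus(pos=100 + i, vaf=vaf)
            has_cosmic = rng.random() < 0.5
            ann = make_annotation(
                v.variant,
                cosmic_id="C1" if has_cosmic else None,
                cosmic_count=int(rng.integers(1, 20)) if has_cosmic else 0,
                dbsnp_id="rs1" if rng.random() < 0.5 else None,
                local_db_af=0.005 if rng.random() < 0.2 else None,
            )
            categories.append(classify_variant(v, ann, CFG).category)
        assert all(isinstance(c, Category) for c in categories)
        n_somatic = sum(c in SOMATIC_FAMILY for c in categories)
        n_germline = sum(c in GERMLINE_FAMILY for c in categories)
        assert n_somatic + n_germline == n

    def test_filter_monotonicity(self):
        """Loosening detection thresholds never removes a kept variant;
        loosening the population cutoff never adds a dropped one."""
        rng = np.random.default_rng(1)
        variants = [
            make_consensus(pos=100 + i, vaf=float(rng.uniform(0, 0.3)),
                           alt_depth=int(rng.integers(0, 40)))
            for i in range(100)
        ]
        anns = {
            v.variant.key: make_annotation(
                v.variant,
                pop_afs={("gnomad_genome", "ALL"): float(rng.uniform(0, 0.03))},
                dbsnp_id="rs1",
            )
            for v in variants
        }
        def kept(cfg):
            classified, _ = run_filters_and_classify(variants, anns, cfg)
            return {cv.consensus.variant.key for cv in classified}

        strict = kept(FilterConfig(min_vaf=0.05, min_alt_reads=12, max_pop_af=0.01))
        loose_detection = kept(FilterConfig(min_vaf=0.01, min_alt_reads=5, max_pop_af=0.01))
        tight_pop = kept(FilterConfig(min_vaf=0.05, min_alt_reads=12, max_pop_af=0.005))
        assert strict <= loose_detection
        assert tight_pop <= strict


class TestGermlineHardFilters:
    def test_low_qual_fails(self):
        decision = apply_germline_hard_filters({"qual": 29.0}, "snp")
        assert not decision.keep and decision.reasons == ("low_qual",)

    def test_snp_qd_threshold(self):
        metrics = {"qual": 50.0, "QD": 1.9, "FS": 10.0, "MQ": 60.0}
        decision = apply_germline_hard_filters(metrics, "snp")
        assert decision.reasons == ("QD",)

    def test_class_specific_fs_bound(self):
        metrics = {"qual": 50.0, "FS": 100.0}
        assert apply_germline_hard_filters(metrics, "indel").keep
        assert not apply_germline_hard_filters(metrics, "snp").keep

    def test_absent_metrics_are_not_violations(self):
        assert apply_germline_hard_filters({"qual": 45.0}, "snp").keep

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError, match="mnv"):
            apply_germline_hard_filters({"qual": 50.0}, "mnv")
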