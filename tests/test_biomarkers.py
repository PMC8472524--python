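"""Knowledge-base matching, cohort summaries, concordance statistics."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_annotation, make_consensus
from panelclassify import fixture_path
from panelclassify.biomarkers import (
    EvidenceTier,
    biomarker_fraction,
    gene_tumor_matrix,
    load_knowledge_base,
    match_biomarkers,
    percent,
    set_concordance,
    summarize_classification,
    vaf_concordance,
)
from panelclassify.classify import Category, ClassifiedVariant

KB_HEADER = "gene\tmatch_kind\tprotein_change\tdrug\teffect\tevidence_tier\ttumor_types\n"


def classified(
    gene="KRAS",
    protein_change="G12D",
    category=Category.SOMATIC,
    consequence="missense",
    sample_id="S1",
    pos=100,
    vaf=0.2,
):
    consensus = make_consensus(pos=pos, vaf=vaf, sample_id=sample_id)
    ann = make_annotation(
        consensus.variant, gene=gene, protein_change=protein_change, consequence=consequence
    )
    return ClassifiedVariant(consensus, ann, category, ("R6_fired",))


class TestKnowledgeBase:
    def test_packaged_guideline_table_has_kras_g12d(self):
        kb = load_knowledge_base(fixture_path("kb_table3.tsv"))
        rules = [r for r in kb if r.gene == "KRAS" and r.protein_change == "G12D"]
        assert {r.drug for r in rules} == {"Cetuximab", "Panitumumab"}
        assert all(r.effect == "resistant" for r in rules)
        assert all(r.evidence_tier is EvidenceTier.FDA_GUIDELINES for r in rules)

    def test_duplicates_collapse_to_highest_tier(self, tmp_path):
        path = tmp_path / "kb.tsv"
        path.write_text(
            KB_HEADER
            + "KRAS\texact_protein_change\tG12D\tCetuximab\tresistant\tearly_trials\t\n"
            + "KRAS\texact_protein_change\tG12D\tCetuximab\tresistant\tfda_guidelines\t\n"
        )
        (rule,) = load_knowledge_base(path)
        assert rule.evidence_tier is EvidenceTier.FDA_GUIDELINES

    def test_unknown_tier_rejected(self, tmp_path):
        path = tmp_path / "kb.tsv"
        path.write_text(KB_HEADER + "KRAS\tgene_level\t\tX\tresistant\tphase4\t\n")
        with pytest.raises(ValueError, match="phase4"):
            load_knowledge_base(path)

    def test_unknown_effect_rejected(self, tmp_path):
        path = tmp_path / "kb.tsv"
        path.write_text(KB_HEADER + "KRAS\tgene_level\t\tX\tneutral\tfda_guidelines\t\n")
        with pytest.raises(ValueError, match="neutral"):
            load_knowledge_base(path)

    def test_tier_ordering_is_total(self):
        tiers = list(EvidenceTier)
        assert sorted(tiers) == [
            EvidenceTier.PRE_CLINICAL,
            EvidenceTier.CASE_REPORT,
            EvidenceTier.EARLY_TRIALS,
            EvidenceTier.LATE_TRIALS,
            EvidenceTier.CLINICAL_GUIDELINES,
            EvidenceTier.FDA_GUIDELINES,
        ]
        for a in tiers:
            for b in tiers:
                assert (a < b) or (a > b) or (a == b)


class TestMatchBiomarkers:
    def test_kras_g12d_hits_guideline_rules(self):
        kb = load_knowledge_base(fixture_path("kb_table3.tsv"))
        hits = match_biomarkers([classified()], kb)
        by_drug = {h.drug: h for h in hits}
        assert by_drug["Cetuximab"].effect == "resistant"
        assert by_drug["Cetuximab"].evidence_tier is EvidenceTier.FDA_GUIDELINES

    def test_tp53_has_no_drug_rules_in_panel_table(self):
        kb = load_knowledge_base(fixture_path("kb_table1.tsv"))
        assert match_biomarkers([classified(gene="TP53", protein_change="R175H")], kb) == []

    def test_exact_and_gene_level_dedup_keeps_higher_tier(self, tmp_path):
        path = tmp_path / "kb.tsv"
        path.write_text(
            KB_HEADER
            + "KRAS\texact_protein_change\tG12D\tCetuximab\tresistant\tearly_trials\t\n"
            + "KRAS\tgene_level\t\tCetuximab\tresistant\tcase_report\t\n"
        )
        hits = match_biomarkers([classified()], load_knowledge_base(path))
        assert len(hits) == 1
        assert hits[0].evidence_tier is EvidenceTier.EARLY_TRIALS
        assert hits[0].matched_by == "exact_protein_change"

    def test_gene_level_needs_protein_affecting_consequence(self, tmp_path):
        path = tmp_path / "kb.tsv"
        path.write_text(KB_HEADER + "KRAS\tgene_level\t\tCetuximab\tresistant\tfda_guidelines\t\n")
        kb = load_knowledge_base(path)
        assert match_biomarkers([classified(consequence="synonymous")], kb) == []
        assert len(match_biomarkers([classified(consequence="frameshift_del")], kb)) == 1

    def test_only_somatic_family_eligible_by_default(self):
        kb = load_knowledge_base(fixture_path("kb_table3.tsv"))
        germline = classified(category=Category.GERMLINE, vaf=0.5)
        assert match_biomarkers([germline], kb) == []
        assert len(match_biomarkers([germline], kb, somatic_only=False)) > 0

    def test_biomarker_fraction_bounds(self):
        kb = load_knowledge_base(fixture_path("kb_table3.tsv"))
        variants = [classified(), classified(gene="GENEX", protein_change="A1B", pos=200)]
        hits = match_biomarkers(variants, kb)
        fraction = biomarker_fraction(variants, hits)
        assert fraction == 0.5


class TestSummaries:
    def test_total_vs_unique(self):
        variants = [classified(sample_id=s) for s in ("S1", "S2", "S3")]
        table = summarize_classification(variants).set_index("category")
        assert table.loc["somatic", "total"] == 3
        assert table.loc["somatic", "unique"] == 1

    def test_empty_input_gives_all_zero_table(self):
        table = summarize_classification([])
        assert (table["total"] == 0).all() and len(table) == 7  # 6 categories + total

    def test_permutation_invariance(self):
        variants = [
            classified(sample_id=f"S{i}", pos=100 + i % 4, category=c)
            for i, c in enumerate(
                [Category.SOMATIC, Category.GERMLINE, Category.PUTATIVE_SOMATIC] * 4
            )
        ]
        a = summarize_classification(variants)
        b = summarize_classification(list(reversed(variants)))
        pd.testing.assert_frame_equal(a, b)

    def test_gene_tumor_matrix_counts_and_marginals(self):
        meta = {"S1": "gallbladder", "S2": "breast"}
        variants = [
            classified(gene="TP53", sample_id="S1", pos=101),
            classified(gene="TP53", sample_id="S2", pos=102),
            classified(gene="KRAS", sample_id="S1", pos=103),
        ]
        m = gene_tumor_matrix(variants, meta)
        assert m.total == 3
        assert m.gene_marginals["TP53"] == 2
        assert m.matrix.loc["KRAS", "gallbladder"] == 1

    def test_single_variant_matrix(self):
        m = gene_tumor_matrix([classified(sample_id="S1")], {"S1": "breast"})
        assert m.total == 1 and m.tumor_marginals["breast"] == 1

    def test_missing_sample_metadata_lists_ids(self):
        with pytest.raises(KeyError, match="S1"):
            gene_tumor_matrix([classified(sample_id="S1")], {})

    def test_cell_sums_equal_variant_count_on_random_cohort(self):
        rng = np.random.default_rng(3)
        genes = ["TP53", "KRAS", "BRCA1", "PIK3CA"]
        meta = {f"S{i}": t for i, t in enumerate(["breast", "ovary", "colorectal"] * 3)}
        variants = [
            classified(
                gene=genes[rng.integers(len(genes))],
                sample_id=f"S{rng.integers(9)}",
                pos=100 + i,
            )
            for i in range(60)
        ]
        m = gene_tumor_matrix(variants, meta)
        assert m.total == 60
        assert m.by_consequence.to_numpy().sum() == 60
        assert m.gene_marginals.sum() == m.tumor_marginals.sum() == 60


class TestStatistics:
    @pytest.mark.parametrize(
        "n, d, decimals, expected",
        [(137, 197, 1, 69.5), (116, 164, 0, 71.0), (111, 131, 0, 85.0), (1, 3, 1, 33.3),
         (15, 19, 0, 79.0), (79, 89, 0, 89.0), (2.5, 1000, 1, 0.3)],  # half-up at the edge
    )
    def test_percent_half_up(self, n, d, decimals, expected):
        assert percent(n, d, decimals) == expected

    def test_percent_zero_denominator(self):
        with pytest.raises(ZeroDivisionError):
            percent(1, 0)

    def test_pearson_limits(self):
        x = [0.1, 0.2, 0.3, 0.4]
        assert vaf_concordance(zip(x, x)) == (pytest.approx(1.0), 4)
        r, _ = vaf_concordance(zip(x, [-v for v in x]))
        assert r == pytest.approx(-1.0)

    def test_pearson_matches_textbook_formula(self):
        rng = np.random.default_rng(5)
        x, y = rng.uniform(0, 1, 30), rng.uniform(0, 1, 30)
        r, n = vaf_concordance(zip(x, y))
        cov = np.mean((x - x.mean()) * (y - y.mean()))
        oracle = cov / (x.std() * y.std())
        assert n == 30 and abs(r - oracle) < 1e-12

    def test_pearson_degenerate_inputs(self):
        with pytest.raises(ValueError):
            vaf_concordance([(0.1, 0.2)])
        with pytest.raises(ValueError):
            vaf_concordance([(0.1, 0.2), (0.1, 0.3)])

    def test_set_concordance(self):
        full = set_concordance(range(7), range(7))
        assert (full.shared, full.jaccard) == (7, 1.0)
        disjoint = set_concordance({1, 2}, {3, 4})
        assert (disjoint.shared, disjoint.jaccard) == (0, 0.0)
        partial = set_concordance({"v1", "v2", "v3"}, {"v2", "v3", "v4"})
        assert (partial.shared, partial.only_a, partial.only_b, partial.jaccard) == (2, 1, 1, 0.5)
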