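"""Family-level diagnosis aggregation, labels, summaries and the exact test."""

from __future__ import annotations

from fractions import Fraction
from math import comb

import pytest

from conftest import make_singleton, make_trio, trio_variant
from mitodx.aggregate import analyse_bundle, compare_strata, label_mitochondrial, summarise_cohort
from mitodx.types import CuratedLists, Panel, ReviewFlags

PANEL = {"p1": Panel("p1", "panel", {"GENE1": "green"})}
CURATED = CuratedLists(pathogenic_mtdna=[], clinvar_plp=set(), mito_genes={"AARS2"})

P = [("PVS1", None), ("PS3", None)]
LP = [("PS3", None), ("PM2", None)]
VUS = [("PM2", None)]


def comphet(bundle, gene="GENE1", classes=(P, LP), consequences=("nonsense", "missense")):
    v1 = trio_variant(bundle, "het", "het", "hom_ref", consequence=consequences[0], gene=gene, pos=1000)
    v2 = trio_variant(bundle, "het", "hom_ref", "het", consequence=consequences[1], gene=gene, pos=2000)
    bundle.nuclear_variants = [v1, v2]
    bundle.evidence = {v1.key: list(classes[0]), v2.key: list(classes[1])}
    bundle.applied_panel_ids = ["p1"]
    return bundle


class TestAggregateFamily:
    def test_two_plp_in_trans_is_definite_biallelic(self):
        [d] = analyse_bundle(comphet(make_trio()), PANEL, CURATED)
        assert (d.confidence, d.inheritance, d.route) == ("definite", "biallelic", "tier12")

    def test_p_plus_vus_in_trans_is_probable(self):
        [d] = analyse_bundle(comphet(make_trio(), classes=(P, VUS)), PANEL, CURATED)
        assert d.confidence == "probable"

    def test_two_vus_parents_untested_is_possible_presumed_biallelic(self):
        b = make_singleton()
        v1 = trio_variant(b, "het", consequence="missense", pos=1000)
        v2 = trio_variant(b, "het", consequence="missense", pos=2000)
        b.nuclear_variants = [v1, v2]
        b.evidence = {v1.key: list(VUS), v2.key: list(VUS)}
        b.applied_panel_ids = ["p1"]
        [d] = analyse_bundle(b, PANEL, CURATED)
        assert (d.confidence, d.inheritance) == ("possible", "biallelic")

    def test_variants_in_cis_rejected(self):
        b = make_trio()
        v1 = trio_variant(b, "het", "het", "hom_ref", gene="GENE1", pos=1000)
        v2 = trio_variant(b, "het", "het", "hom_ref", gene="GENE1", pos=2000)
        b.nuclear_variants = [v1, v2]
        b.evidence = {v1.key: list(P), v2.key: list(VUS)}
        b.applied_panel_ids = ["p1"]
        assert analyse_bundle(b, PANEL, CURATED) == []

    def test_unreviewed_variant_cannot_support_diagnosis(self):
        b = make_trio()
        v = trio_variant(b, "het", "het", "hom_ref", consequence="nonsense")
        b.nuclear_variants = [v]
        b.evidence = {}
        b.applied_panel_ids = ["p1"]
        assert analyse_bundle(b, PANEL, CURATED) == []

    def test_benign_classification_excluded(self):
        b = make_trio()
        v = trio_variant(b, "het", "het", "hom_ref", consequence="nonsense")
        b.nuclear_variants = [v]
        b.evidence = {v.key: [("BA1", None)]}
        b.applied_panel_ids = ["p1"]
        assert analyse_bundle(b, PANEL, CURATED) == []

    def test_two_gene_family_yields_two_diagnoses(self):
        panels = {"p1": Panel("p1", "p", {"GENE1": "green", "GENE2": "green"})}
        b = comphet(make_trio())
        v3 = trio_variant(b, "het", "hom_ref", "hom_ref", gene="GENE2", pos=9000)
        b.nuclear_variants.append(v3)
        b.evidence[v3.key] = list(P)
        ds = analyse_bundle(b, panels, CURATED)
        assert len(ds) == 2
        assert {d.genes[0] for d in ds} == {"GENE1", "GENE2"}

    def test_review_adjustment_moves_confidence(self):
        b = comphet(make_trio())
        b.review["GENE1"] = ReviewFlags(adjustment=-1)
        [d] = analyse_bundle(b, PANEL, CURATED)
        assert d.confidence == "probable"

    def test_upgrading_vus_to_lp_never_lowers_confidence(self):
        rank = {"possible": 1, "probable": 2, "definite": 3}
        before = analyse_bundle(comphet(make_trio(), classes=(P, VUS)), PANEL, CURATED)
        after = analyse_bundle(comphet(make_trio(), classes=(P, LP)), PANEL, CURATED)
        assert rank[after[0].confidence] >= rank[before[0].confidence]


class TestMitochondrialLabel:
    def test_curated_nuclear_gene(self):
        assert label_mitochondrial(["AARS2"], CURATED.mito_genes) is True

    def test_non_mitochondrial_gene(self):
        assert label_mitochondrial(["BBS1"], CURATED.mito_genes) is False

    def test_mtdna_encoded_gene_always_mitochondrial(self):
        assert label_mitochondrial(["MT-ND3"], set()) is True


class TestSummaries:
    def test_empty_cohort_all_zero(self):
        s = summarise_cohort({}, {})
        assert (s.n_families, s.n_diagnosed, s.n_definite, s.distinct_genes) == (0, 0, 0, 0)

    def test_single_diagnosed_family_yield(self):
        b = comphet(make_trio())
        ds = analyse_bundle(b, PANEL, CURATED)
        s = summarise_cohort({b.family_id: ds}, {b.family_id: b.members})
        assert s.n_diagnosed == 1 and s.n_definite == 1
        assert s.yield_by_stratum["structure:trio_quad"] == (1, 1)

    def test_family_counts_once_by_best_confidence(self, fixture_analysis):
        results, summary = fixture_analysis
        assert summary.n_definite + summary.n_probable + summary.n_possible == summary.n_diagnosed
        assert sum(summary.route_counts.values()) == summary.n_diagnosed


class TestCompareStrata:
    def test_identical_proportions_give_p_one(self):
        p, p1, p2 = compare_strata(5, 10, 5, 10)
        assert p == pytest.approx(1.0)
        assert p1 == p2 == 0.5

    def test_small_table_matches_full_enumeration(self):
        """(2 of 4) vs (1 of 4): enumerate all tables with fixed margins."""
        p, _, _ = compare_strata(2, 4, 1, 4)
        r1, r2, c1 = 4, 4, 3
        denom = comb(r1 + r2, c1)
        probs = {x: Fraction(comb(r1, x) * comb(r2, c1 - x), denom)
                 for x in range(max(0, c1 - r2), min(r1, c1) + 1)}
        expected = float(sum(q for q in probs.values() if q <= probs[2]))
        assert p == pytest.approx(expected, abs=1e-12)

    def test_zero_margin_is_error(self):
        with pytest.raises(ValueError):
            compare_strata(0, 10, 0, 10)
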