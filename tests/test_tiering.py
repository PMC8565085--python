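"""Tier assignment, de novo detection and candidate channels.

The central check is oracle equivalence: ``assign_tier`` must agree
with an independent brute-force transcription of the tier definitions
on randomly drawn (consequence, frequency, genotype configuration,
panel membership) tuples.
"""

from __future__ import annotations

import numpy as np
import pytest

from conftest import make_singleton, make_trio, trio_variant
from mitodx.tiering import (
    assign_tier,
    clinvar_intersect,
    detect_de_novo,
    external_rank_top10,
    segregation_consistent,
    tier_family,
)
from mitodx.types import CuratedLists, FamilyMember, FamilyBundle, Panel, ValidationError

PANEL = Panel("p1", "panel", {"GENE1": "green", "AMBERG": "amber"})
CONSEQUENCES = [
    "nonsense", "frameshift", "essential_splice_donor", "essential_splice_acceptor",
    "splice_region", "missense", "inframe_indel", "synonymous", "intronic", "other",
]
LOF = {"nonsense", "frameshift", "essential_splice_donor", "essential_splice_acceptor"}


class TestDeNovo:
    def test_trio_definition_case(self):
        b = make_trio()
        v = trio_variant(b, "het", "hom_ref", "hom_ref", depth=10, gq=20)
        assert detect_de_novo(v, b) is True

    def test_duo_never_de_novo(self):
        fid = "D1"
        members = [
            FamilyMember(fid, f"{fid}_P", None, f"{fid}_MO", "male", True, 5, True),
            FamilyMember(fid, f"{fid}_MO", None, None, "female", False, 30),
        ]
        b = FamilyBundle(fid, members)
        v = trio_variant(b, "het", gt_mother="hom_ref")
        assert detect_de_novo(v, b) is False

    def test_inherited_not_de_novo(self):
        b = make_trio()
        assert detect_de_novo(trio_variant(b, "het", "het", "hom_ref"), b) is False

    def test_qc_floor_blocks_call(self):
        b = make_trio()
        v = trio_variant(b, "het", depth=9)
        assert detect_de_novo(v, b) is False
        v = trio_variant(b, "het", gq=19)
        assert detect_de_novo(v, b) is False


class TestSegregation:
    def test_dominant_unaffected_carrier_fails(self):
        b = make_trio()
        assert segregation_consistent(trio_variant(b, "het", "het"), b, "dominant") is False

    def test_biallelic_carrier_parent_permitted(self):
        b = make_trio()
        assert segregation_consistent(trio_variant(b, "hom_alt", "het", "het"), b, "biallelic")

    def test_vacuous_when_only_proband_genotyped(self):
        b = make_singleton()
        v = trio_variant(b, "het")
        assert segregation_consistent(v, b, "dominant") is True

    def test_x_linked_unaffected_hemizygous_male_fails(self):
        b = make_trio()
        v = trio_variant(b, "het", gt_father="hemi", chrom="X")
        assert segregation_consistent(v, b, "x_linked") is False


class TestAssignTier:
    def test_inherited_nonsense_green_panel_is_tier1(self):
        b = make_trio()
        v = trio_variant(b, "het", "het", "hom_ref", consequence="nonsense")
        t = assign_tier(v, b, [PANEL])
        assert t.tier == 1 and "lof" in t.rule_fired

    def test_inherited_missense_panel_is_tier2(self):
        b = make_trio()
        v = trio_variant(b, "het", "het", "hom_ref", af=1e-5)
        assert assign_tier(v, b, [PANEL]).tier == 2

    def test_de_novo_missense_panel_is_tier1(self):
        b = make_trio()
        v = trio_variant(b, "het")
        t = assign_tier(v, b, [PANEL])
        assert t.tier == 1 and t.de_novo

    def test_common_missense_is_tier4_anywhere(self):
        b = make_trio()
        v = trio_variant(b, "het", af=0.05)
        assert assign_tier(v, b, [PANEL]).tier == 4

    def test_rare_synonymous_off_panel_is_tier3(self):
        b = make_trio()
        v = trio_variant(b, "het", consequence="synonymous", gene="OFFPANEL")
        assert assign_tier(v, b, [PANEL]).tier == 3

    def test_non_pass_variant_rejected_not_tiered(self):
        b = make_trio()
        v = trio_variant(b, "het", filter_pass=False)
        with pytest.raises(ValidationError):
            assign_tier(v, b, [PANEL])
        assert tier_family(b, [PANEL]) == []  # skipped, never tiered

    def test_amber_gene_needs_config_to_reach_tier2(self):
        b = make_trio()
        v = trio_variant(b, "het", "het", "hom_ref", gene="AMBERG")
        assert assign_tier(v, b, [PANEL]).tier == 3
        assert assign_tier(v, b, [PANEL], panel_min_confidence="amber").tier == 2


def oracle_tier(consequence, af, hom, de_novo, seg_ok, green_panel):
    """Brute-force transcription of the tier definitions."""
    ceiling = 0.01 if hom else 0.001
    if af >= ceiling:
        return 4
    if not seg_ok:
        return 4
    if green_panel and (consequence in LOF or (de_novo and consequence in {"missense", "splice_region"})):
        return 1
    if green_panel and consequence in {"missense", "splice_region", "inframe_indel"}:
        return 2
    return 3


def test_oracle_equivalence_on_random_tuples():
    """assign_tier agrees with the brute-force oracle on 1,000 random
    genotype/frequency/panel configurations; zero disagreements."""
    rng = np.random.default_rng(20240217)
    panel = Panel("p", "p", {"GENE1": "green"})
    disagreements = 0
    for i in range(1000):
        consequence = CONSEQUENCES[rng.integers(len(CONSEQUENCES))]
        af = float(rng.choice([0.0, 1e-5, 5e-4, 2e-3, 5e-3, 0.02, 0.1]))
        on_panel = bool(rng.random() < 0.5)
        gene = "GENE1" if on_panel else "OFF"
        config = rng.integers(5)
        b = make_trio(f"R{i}")
        if config == 0:  # de novo het
            v = trio_variant(b, "het", "hom_ref", "hom_ref", consequence=consequence, gene=gene, af=af)
            de_novo, hom = True, False
        elif config == 1:  # inherited het from carrier father
            v = trio_variant(b, "het", "het", "hom_ref", consequence=consequence, gene=gene, af=af)
            de_novo, hom = False, False
        elif config == 2:  # homozygous, both parents carriers
            v = trio_variant(b, "hom_alt", "het", "het", consequence=consequence, gene=gene, af=af)
            de_novo, hom = False, True
        elif config == 3:  # unaffected parent is homozygous: fails every model
            v = trio_variant(b, "het", "hom_alt", "hom_ref", consequence=consequence, gene=gene, af=af)
            de_novo, hom = False, False
        else:  # singleton
            b = make_singleton(f"R{i}")
            v = trio_variant(b, "het", consequence=consequence, gene=gene, af=af)
            de_novo, hom = False, False
        seg_ok = config != 3
        got = assign_tier(v, b, [panel]).tier
        want = oracle_tier(consequence, af, hom, de_novo, seg_ok, on_panel)
        disagreements += got != want
    assert disagreements == 0


def test_raising_af_never_lowers_tier_number():
    b = make_trio()
    for consequence in ("nonsense", "missense", "synonymous"):
        tiers = []
        for af in (0.0, 1e-5, 5e-4, 2e-3, 0.02, 0.2):
            v = trio_variant(b, "het", "het", "hom_ref", consequence=consequence, af=af)
            tiers.append(assign_tier(v, b, [PANEL]).tier)
        assert tiers == sorted(tiers)


def test_off_panel_never_tier_1_or_2():
    rng = np.random.default_rng(7)
    for i in range(200):
        b = make_trio(f"Q{i}")
        consequence = CONSEQUENCES[rng.integers(len(CONSEQUENCES))]
        child = ["het", "hom_alt"][rng.integers(2)]
        v = trio_variant(b, child, "het", "het", consequence=consequence, gene="OFF",
                         af=float(rng.choice([0.0, 1e-4, 0.02])))
        assert assign_tier(v, b, [PANEL]).tier >= 3


def test_tiering_partitions_pass_variants(fixture_cohort):
    c = fixture_cohort
    panels = [c.panels[pid] for pid in ("mito", "other")]
    for fid in list(c.bundles)[:40]:
        b = c.bundles[fid]
        n_pass = sum(v.filter_pass for v in b.nuclear_variants)
        assignments = tier_family(b, panels)
        assert len(assignments) == n_pass
        assert all(t.tier in (1, 2, 3, 4) for t in assignments)


class TestChannels:
    def test_clinvar_intersect_is_allele_exact(self):
        b = make_trio()
        v = trio_variant(b, "het")
        hit_table = CuratedLists(pathogenic_mtdna=[], clinvar_plp={("1", 1000, "A", "G")})
        miss_table = CuratedLists(pathogenic_mtdna=[], clinvar_plp={("1", 1000, "A", "T")})
        assert len(clinvar_intersect([v], hit_table)) == 1
        assert clinvar_intersect([v], miss_table) == []
        assert clinvar_intersect([v], CuratedLists(pathogenic_mtdna=[], clinvar_plp=set())) == []

    def test_clinvar_build_mismatch_is_error(self):
        b = make_trio()
        v = trio_variant(b, "het")
        table = CuratedLists(pathogenic_mtdna=[], clinvar_plp=set(), clinvar_build="GRCh37")
        with pytest.raises(ValidationError):
            clinvar_intersect([v], table, build="GRCh38")

    def test_external_rank_keeps_top_10_only(self):
        b = make_trio()
        variants = {}
        ranks = []
        for i in range(25):
            v = trio_variant(b, "het", pos=2000 + i)
            variants[v.key] = v
            ranks.append((v.key, i + 1))
        assert len(external_rank_top10(ranks, variants)) == 10
        assert len(external_rank_top10(ranks[:3], variants)) == 3
        assert external_rank_top10([], variants) == []

    def test_duplicate_rank_is_error(self):
        b = make_trio()
        v = trio_variant(b, "het")
        with pytest.raises(ValidationError):
            external_rank_top10([(v.key, 1), (v.key, 1)], {v.key: v})
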