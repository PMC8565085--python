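"""CNV exon-overlap triage and STR expansion classification."""

from __future__ import annotations

import numpy as np
import pytest

from mitodx.io import default_data_path, read_str_loci
from mitodx.sv_str import classify_str, classify_str_table, filter_cnvs, merge_exons
from mitodx.types import CnvCall, ExonModel, Panel, StrGenotype

PANEL = Panel("p", "p", {"GENEA": "green", "GENEB": "green"})
MODELS = [
    ExonModel("GENEA", [("1", 1000, 1200), ("1", 2000, 2200), ("1", 3000, 3200)]),
    ExonModel("GENEB", [("2", 5000, 5300)]),
    ExonModel("OFFPANEL", [("1", 1000, 1200)]),
]


@pytest.fixture(scope="module")
def loci():
    return read_str_loci(default_data_path("str_loci.tsv"))


class TestCnvFilter:
    def test_pass_exon_deletion_retained_with_annotation(self):
        c = CnvCall("1", 1950, 2100, "loss", True, "S")
        [ann] = filter_cnvs([c], MODELS, [PANEL])
        assert ann.gene_exons == {"GENEA": [1]}

    def test_non_pass_whole_gene_deletion_dropped(self):
        c = CnvCall("1", 500, 4000, "loss", False, "S")
        assert filter_cnvs([c], MODELS, [PANEL]) == []

    def test_wholly_intronic_deletion_dropped(self):
        c = CnvCall("1", 1300, 1900, "loss", True, "S")
        assert filter_cnvs([c], MODELS, [PANEL]) == []

    def test_off_panel_gene_does_not_rescue(self):
        c = CnvCall("1", 1000, 1100, "loss", True, "S")
        panel_b_only = Panel("p", "p", {"GENEB": "green"})
        assert filter_cnvs([c], MODELS, [panel_b_only]) == []

    def test_single_base_overlap_counts(self):
        c = CnvCall("1", 1199, 1500, "loss", True, "S")
        assert len(filter_cnvs([c], MODELS, [PANEL])) == 1

    def test_widening_never_removes_an_annotation(self):
        base = CnvCall("1", 2100, 2150, "loss", True, "S")
        [ann0] = filter_cnvs([base], MODELS, [PANEL])
        wide = CnvCall("1", 900, 3500, "loss", True, "S")
        [ann1] = filter_cnvs([wide], MODELS, [PANEL])
        for gene, exons in ann0.gene_exons.items():
            assert set(exons) <= set(ann1.gene_exons[gene])

    def test_overlap_agrees_with_per_base_oracle(self):
        """500 random interval/exon pairs against per-base intersection."""
        rng = np.random.default_rng(99)
        for _ in range(500):
            s, e = sorted(rng.integers(0, 400, size=2))
            e = int(e) + 1
            xs, xe = sorted(rng.integers(0, 400, size=2))
            xe = int(xe) + 1
            model = [ExonModel("G", [("1", int(xs), xe)])]
            panel = Panel("p", "p", {"G": "green"})
            call = CnvCall("1", int(s), e, "loss", True, "S")
            got = bool(filter_cnvs([call], model, [panel]))
            want = bool(set(range(int(s), e)) & set(range(int(xs), xe)))
            assert got == want

    def test_merge_exons_collapses_overlaps(self):
        merged = merge_exons([("1", 0, 10), ("1", 5, 20), ("1", 30, 40), ("2", 0, 5)])
        assert merged == [("1", 0, 20), ("1", 30, 40), ("2", 0, 5)]


class TestStr:
    def test_htt_forty_repeats_full_mutation_causative(self, loci):
        res = classify_str(StrGenotype("S", "HTT", 40, 17, "confirmed"), loci["HTT"], 71)
        assert res.classification == "full_mutation" and res.causative

    def test_htt_twenty_repeats_normal(self, loci):
        res = classify_str(StrGenotype("S", "HTT", 20, 17), loci["HTT"])
        assert res.classification == "normal" and not res.causative

    def test_rejected_on_visual_review_not_causative(self, loci):
        res = classify_str(StrGenotype("S", "HTT", 44, 17, "rejected"), loci["HTT"])
        assert res.classification == "full_mutation" and not res.causative

    def test_premutation_band(self, loci):
        res = classify_str(StrGenotype("S", "HTT", 38, 17), loci["HTT"])
        assert res.classification == "premutation" and not res.causative

    def test_recessive_locus_needs_both_alleles_expanded(self, loci):
        mono = classify_str(StrGenotype("S", "FXN", 300, 20), loci["FXN"])
        assert mono.classification == "full_mutation" and not mono.causative
        bi = classify_str(StrGenotype("S", "FXN", 300, 80), loci["FXN"])
        assert bi.causative

    def test_classification_monotone_in_repeat_count(self, loci):
        order = {"normal": 0, "premutation": 1, "full_mutation": 2}
        for locus, d in loci.items():
            ranks = [
                order[classify_str(StrGenotype("S", locus, r, 5), d).classification]
                for r in range(1, d.full_min + 30)
            ]
            assert ranks == sorted(ranks)

    def test_thirteen_loci_shipped(self, loci):
        assert len(loci) == 13
        assert set(loci) == {
            "HTT", "AR", "ATN1", "ATXN1", "ATXN2", "ATXN3", "ATXN7",
            "CACNA1A", "TBP", "C9orf72", "FXN", "FMR1", "DMPK",
        }

    def test_unknown_locus_is_error(self, loci):
        with pytest.raises(KeyError):
            classify_str_table([StrGenotype("S", "NOPE", 10, 10)], loci)
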