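"""HPO ancestor-system mapping and the modified mitochondrial score."""

from __future__ import annotations

import numpy as np
import pytest

from mitodx.phenotype import PHENOTYPIC_ABNORMALITY, band_for_total, mdc_score, system_profile, term_systems
from mitodx.synthetic import SYSTEMS
from mitodx.types import MdcConfig, PhenotypePacket


def packet(terms):
    return PhenotypePacket(sample_id="S", hpo_terms=set(terms))


class TestTermSystems:
    def test_single_lineage_gives_singleton(self, ontology):
        assert term_systems("HP:0001250", ontology) == {"HP:0000707"}  # seizure -> nervous

    def test_two_parent_lineages_give_two_systems(self, ontology):
        # hearing impairment sits under both the ear and the nervous system
        assert term_systems("HP:0000365", ontology) == {"HP:0000598", "HP:0000707"}

    def test_root_maps_to_no_system(self, ontology):
        assert term_systems(PHENOTYPIC_ABNORMALITY, ontology) == set()

    def test_system_term_maps_to_itself(self, ontology):
        assert term_systems("HP:0000707", ontology) == {"HP:0000707"}

    def test_unknown_term_is_error(self, ontology):
        with pytest.raises(KeyError):
            term_systems("HP:9999999", ontology)

    def test_agrees_with_transitive_closure_oracle(self, ontology):
        """Brute-force ancestor closure on 200 random terms."""
        edges = [(c, p) for c, p, k in ontology.edges(keys=True) if k == "is_a"]
        parents: dict[str, set[str]] = {}
        for child, parent in edges:
            parents.setdefault(child, set()).add(parent)
        system_ids = {tid for tid, _ in SYSTEMS}

        def closure(term):
            seen, stack = {term}, [term]
            while stack:
                for p in parents.get(stack.pop(), ()):
                    if p not in seen:
                        seen.add(p)
                        stack.append(p)
            return seen

        rng = np.random.default_rng(5)
        nodes = sorted(ontology.nodes)
        for term in rng.choice(nodes, size=200, replace=True):
            assert term_systems(str(term), ontology) == closure(str(term)) & system_ids


class TestSystemProfile:
    def test_all_single_system_terms(self, ontology):
        terms = ["HP:0001250", "HP:0001251", "HP:0002376"]  # all nervous
        assert system_profile(packet(terms), ontology) == {"HP:0000707": 3}

    def test_multi_system_term_counts_in_each(self, ontology):
        prof = system_profile(packet(["HP:0000819"]), ontology)  # diabetes
        assert prof == {"HP:0000818": 1, "HP:0001939": 1}

    def test_empty_packet_empty_profile(self, ontology):
        assert system_profile(packet([]), ontology) == {}


class TestMdcScore:
    def test_empty_packet_unlikely(self, mdc_config):
        s = mdc_score(packet([]), mdc_config)
        assert s.total == 0 and s.band == "unlikely"

    def test_band_cut_points(self):
        bands = [band_for_total(t) for t in range(13)]
        assert bands[:2] == ["unlikely"] * 2
        assert bands[2:5] == ["possible"] * 3
        assert bands[5:8] == ["probable"] * 3
        assert bands[8:] == ["definite"] * 5

    def test_probable_band_at_total_five(self, mdc_config):
        # myopathy (2) + seizure (1) + lactic acidosis (2)
        s = mdc_score(packet(["HP:0003198", "HP:0001250", "HP:0003128"]), mdc_config)
        assert s.total == 5 and s.band == "probable"

    def test_caps_and_clamp(self, mdc_config):
        # every mapped term at once: clinical group 4 + metabolic 4 + morphology 4 = 12
        s = mdc_score(packet(mdc_config.item_map), mdc_config)
        assert s.total == 12 and s.band == "definite"

    def test_unmapped_terms_contribute_nothing(self, mdc_config, ontology):
        s = mdc_score(packet(["HP:0000952", "HP:0001903"]), mdc_config)  # unmapped leaves
        assert s.total == 0

    def test_worked_clamp_example(self):
        config = MdcConfig(
            item_map={
                "T:M1": ("clinical_muscular", 3),
                "T:C1": ("clinical_cns", 2),
                "T:B1": ("metabolic_imaging", 3),
                "T:H1": ("morphology", 1),
            },
            section_caps={s: 4 for s in (
                "clinical_muscular", "clinical_cns", "clinical_multisystem",
                "metabolic_imaging", "morphology")},
        )
        s = mdc_score(packet(["T:M1", "T:C1", "T:B1", "T:H1"]), config)
        # clinical 3+2 clamps to the group cap 4; +3 metabolic +1 morphology
        assert s.total == 8 and s.band == "definite"

    def test_monotone_and_bounded_over_random_packets(self, mdc_config):
        """Adding a term never lowers any section score or the total."""
        rng = np.random.default_rng(42)
        universe = sorted(mdc_config.item_map) + [f"HP:{i:07d}" for i in range(20)]
        for _ in range(2000):
            k = int(rng.integers(0, len(universe)))
            terms = set(rng.choice(universe, size=k, replace=False)) if k else set()
            s0 = mdc_score(packet(terms), mdc_config)
            assert 0 <= s0.total <= 12
            extra = str(rng.choice(universe))
            s1 = mdc_score(packet(terms | {extra}), mdc_config)
            assert s1.total >= s0.total
            for section, value in s0.section_scores.items():
                assert s1.section_scores[section] >= value
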