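"""HPO ancestor-system mapping and the HPO-modified mitochondrial score.

The mitochondrial disease criteria score participants 0-12 across three
clinical sections (muscular, CNS, multisystem — jointly capped), a
metabolic/imaging section and a muscle-morphology section, and band the
total as unlikely (0-1), possible (2-4), probable (5-7) or definite (>=8).
"""

from __future__ import annotations

import networkx as nx

from .types import CLINICAL_SECTIONS, MDC_SECTIONS, MdcConfig, MdcScore, PhenotypePacket

PHENOTYPIC_ABNORMALITY = "HP:0000118"

BANDS = (
    (0, 1, "unlikely"),
    (2, 4, "possible"),
    (5, 7, "probable"),
    (8, 12, "definite"),
)


def band_for_total(total: int) -> str:
    for lo, hi, name in BANDS:
        if lo <= total <= hi:
            return name
    raise ValueError(f"total out of range: {total}")


def term_systems(term: str, ontology: nx.MultiDiGraph, root: str = PHENOTYPIC_ABNORMALITY) -> set[str]:
    """Top-level system terms for ``term``.

    Returns the children of the phenotypic-abnormality root that lie on
    (or equal) any ancestor path of ``term``.  ``ontology`` is an obonet
    graph, whose ``is_a`` edges point from child to parent, so graph
    descendants are ontology ancestors.

    A term with several parent lineages can map to several systems; the
    root itself maps to none.
    """
    if term not in ontology:
        raise KeyError(f"term {term} not found in ontology (obsolete or unknown)")
    systems = {child for child, parent, k in ontology.in_edges(root, keys=True) if k == "is_a"}
    ancestors = nx.descendants(ontology, term) | {term}
    return systems & ancestors


def system_profile(packet: PhenotypePacket, ontology: nx.MultiDiGraph) -> dict[str, int]:
    """Count the packet's terms per ancestor system.

    A term with k ancestor systems contributes one count to each of the
    k systems.
    """
    profile: dict[str, int] = {}
    for term in sorted(packet.hpo_terms):
        for system in term_systems(term, ontology):
            profile[system] = profile.get(system, 0) + 1
    return profile


def mdc_score(packet: PhenotypePacket, config: MdcConfig) -> MdcScore:
    """Score a phenotype packet against the sectioned criteria.

    Each distinct mapped term contributes its points once to its
    section; sections are clamped at their caps, the clinical sections
    are additionally clamped as a group, and the total is clamped at 12.
    Unmapped terms contribute nothing.
    """
    raw: dict[str, int] = {s: 0 for s in MDC_SECTIONS}
    for term in packet.hpo_terms:
        mapped = config.item_map.get(term)
        if mapped is None:
            continue
        section, points = mapped
        raw[section] += points
    capped = {s: min(raw[s], config.section_caps.get(s, config.total_cap)) for s in MDC_SECTIONS}
    clinical = min(sum(capped[s] for s in CLINICAL_SECTIONS), config.clinical_group_cap)
    total = clinical + capped["metabolic_imaging"] + capped["morphology"]
    total = min(total, config.total_cap)
    return MdcScore(section_scores=capped, total=total, band=band_for_total(total))
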