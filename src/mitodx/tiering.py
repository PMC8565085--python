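"""Nuclear variant tiering, de novo detection and candidate channels.

Variants are ranked tier 1 (most likely causative) to tier 4
(unclassified).  Tier 1 is loss-of-function — nonsense, frameshift,
essential splice donor/acceptor — or a trio-confirmed de novo
missense/splice-region change, in a green gene of an applied panel;
tier 2 is missense/splice-region/in-frame in an applied panel gene;
tier 3 is any other rare variant; tier 4 is too common in the
population or inconsistent with segregation in the family.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

from .types import (
    LOF_CONSEQUENCES,
    CandidateChannelHit,
    CuratedLists,
    FamilyBundle,
    NuclearVariant,
    Panel,
    TierAssignment,
    ValidationError,
)

log = logging.getLogger(__name__)

SEGREGATION_MODELS = ("dominant", "biallelic", "x_linked")


@dataclass
class RarityConfig:
    """Population-frequency ceilings for candidate variants.

    Monoallelic (dominant / de novo) candidates must be rarer than
    ``af_monoallelic``; biallelic candidates than ``af_biallelic``.
    Variants with no recorded frequency are treated as unobserved
    (AF 0) for the rarity test.
    """

    af_monoallelic: float = 1e-3
    af_biallelic: float = 1e-2


@dataclass
class DeNovoQc:
    min_depth: int = 10
    min_gq: int = 20


def detect_de_novo(
    variant: NuclearVariant, bundle: FamilyBundle, qc: DeNovoQc | None = None
) -> bool:
    """True iff the proband's allele is trio-confirmed de novo.

    Requires both parents present and genotyped hom_ref and all three
    samples above the depth/GQ floors.  Singletons and duos can never
    be de novo by this test.
    """
    qc = qc or DeNovoQc()
    proband = bundle.proband
    if not variant.carried_by(proband.sample_id):
        return False
    father, mother = bundle.member(proband.father_id), bundle.member(proband.mother_id)
    if father is None or mother is None:
        return False
    for parent in (father, mother):
        if variant.genotypes.get(parent.sample_id, "missing") != "hom_ref":
            return False
    for sample in (proband.sample_id, father.sample_id, mother.sample_id):
        if variant.depth.get(sample, 0) < qc.min_depth or variant.gq.get(sample, 0) < qc.min_gq:
            log.debug("de novo rejected for %s: QC floor failed in %s", variant.key, sample)
            return False
    return True


def segregation_consistent(variant: NuclearVariant, bundle: FamilyBundle, model: str) -> bool:
    """Whether carriage in the family is compatible with ``model``.

    dominant: no unaffected carrier; biallelic: no unaffected hom_alt
    (heterozygous carriers are permitted); x_linked: no unaffected
    hemizygous male.  Ungenotyped members are vacuously consistent.
    """
    if model not in SEGREGATION_MODELS:
        raise ValueError(f"unknown segregation model {model!r}")
    for m in bundle.members:
        if m.affected:
            continue
        gt = variant.genotypes.get(m.sample_id, "missing")
        if model == "dominant" and gt in {"het", "hom_alt", "hemi"}:
            return False
        if model == "biallelic" and gt == "hom_alt":
            return False
        if model == "x_linked" and gt == "hemi" and m.sex == "male":
            return False
    return True


def _green_panel_hits(gene: str, panels: Iterable[Panel], min_confidence: str) -> set[str]:
    allowed = {"green"} if min_confidence == "green" else {"green", "amber"}
    return {p.panel_id for p in panels if p.genes.get(gene) in allowed}


def assign_tier(
    variant: NuclearVariant,
    bundle: FamilyBundle,
    applied_panels: list[Panel],
    rarity: RarityConfig | None = None,
    de_novo_qc: DeNovoQc | None = None,
    panel_min_confidence: str = "green",
) -> TierAssignment:
    """Assign the tier for one PASS variant in the context of its family.

    Raises
    ------
    ValidationError
        If the variant failed the caller FILTER; such variants are
        never tiered.
    """
    if not variant.filter_pass:
        raise ValidationError(f"variant {variant.key} failed caller FILTER; not tiered")
    rarity = rarity or RarityConfig()

    de_novo = detect_de_novo(variant, bundle, de_novo_qc)
    panels_hit = _green_panel_hits(variant.gene, applied_panels, panel_min_confidence)

    af = variant.population_af or 0.0
    hom = variant.genotypes.get(bundle.proband.sample_id) == "hom_alt"
    af_ceiling = rarity.af_biallelic if hom else rarity.af_monoallelic
    rare = af < af_ceiling

    # the x-linked model is vacuous off the X chromosome; testing it there
    # would make "inconsistent under every model" unreachable
    models = SEGREGATION_MODELS if variant.chrom in {"X", "chrX"} else ("dominant", "biallelic")
    consistent = any(segregation_consistent(variant, bundle, m) for m in models)

    if not rare:
        return TierAssignment(variant, 4, "tier4:population_frequency", set(), de_novo, consistent)
    if not consistent:
        return TierAssignment(variant, 4, "tier4:segregation", set(), de_novo, consistent)

    lof = variant.consequence in LOF_CONSEQUENCES
    dn_functional = de_novo and variant.consequence in {"missense", "splice_region"}
    if panels_hit and (lof or dn_functional):
        rule = "tier1:lof_panel" if lof else "tier1:de_novo_panel"
        return TierAssignment(variant, 1, rule, panels_hit, de_novo, consistent)
    if panels_hit and variant.consequence in {"missense", "splice_region", "inframe_indel"}:
        return TierAssignment(variant, 2, "tier2:functional_panel", panels_hit, de_novo, consistent)
    return TierAssignment(variant, 3, "tier3:other_rare", set(), de_novo, consistent)


def tier_family(
    bundle: FamilyBundle,
    applied_panels: list[Panel],
    rarity: RarityConfig | None = None,
    de_novo_qc: DeNovoQc | None = None,
) -> list[TierAssignment]:
    """Tier every PASS variant of a family; non-PASS variants are skipped."""
    out = []
    for v in bundle.nuclear_variants:
        if not v.filter_pass:
            log.debug("skipping non-PASS variant %s", v.key)
            continue
        out.append(assign_tier(v, bundle, applied_panels, rarity, de_novo_qc))
    return out


def clinvar_intersect(
    variants: Iterable[NuclearVariant],
    curated: CuratedLists,
    build: str = "GRCh38",
) -> list[CandidateChannelHit]:
    """Allele-exact intersection of variants with the ClinVar P/LP table.

    Matching is on the full (chrom, pos, ref, alt) tuple, never on
    position alone.  Both sides must carry the same genome-build label.
    """
    if build != curated.clinvar_build:
        raise ValidationError(
            f"genome build mismatch: variants on {build}, "
            f"ClinVar table on {curated.clinvar_build}"
        )
    hits = []
    for v in variants:
        if (v.chrom, v.pos, v.ref, v.alt) in curated.clinvar_plp:
            hits.append(CandidateChannelHit(v, "clinvar_plp"))
    return hits


def external_rank_top10(
    ranks: Iterable[tuple[str, int]],
    variants_by_key: dict[str, NuclearVariant],
) -> list[CandidateChannelHit]:
    """Hits from an external prioritiser's per-proband ranking, top 10 only.

    ``ranks`` pairs variant keys with ranks for one proband.  A
    duplicated rank is an input error.  An absent/empty rank file is an
    empty channel.
    """
    seen_ranks: set[int] = set()
    hits = []
    for key, rank in ranks:
        if rank in seen_ranks:
            raise ValidationError(f"duplicate prioritiser rank {rank}")
        seen_ranks.add(rank)
        if rank <= 10 and key in variants_by_key:
            hits.append(CandidateChannelHit(variants_by_key[key], "external_rank_top10", rank))
    return hits
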