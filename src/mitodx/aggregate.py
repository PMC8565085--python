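"""Per-family diagnosis aggregation and cohort summaries.

Candidates from every channel (tiered SNVs, ClinVar/prioritiser hits,
CNVs, STR expansions, mtDNA findings) are combined per gene into at most
a few candidate diagnoses, each carrying an inheritance pattern, an
evidence-derived confidence (definite / probable / possible) optionally
adjusted by the clinical-review input, a contribution flag (full or
partial explanation of the phenotype), the analysis route that produced
it, and a mitochondrial / non-mitochondrial label.
"""

from __future__ import annotations

import logging
from typing import Iterable, Optional

from scipy import stats

from .acmg import classify_evidence_map
from .mtdna import MtdnaQcConfig, analyse_mtdna
from .sv_str import AnnotatedCnv, StrResult, classify_str_table, filter_cnvs
from .tiering import (
    DeNovoQc,
    RarityConfig,
    clinvar_intersect,
    detect_de_novo,
    external_rank_top10,
    tier_family,
)
from .types import (
    CandidateChannelHit,
    CandidateDiagnosis,
    CohortSummary,
    CuratedLists,
    FamilyBundle,
    FamilyMember,
    NuclearVariant,
    Panel,
    ReviewFlags,
    TierAssignment,
)

log = logging.getLogger(__name__)

CONFIDENCE_RANK = {"possible": 1, "probable": 2, "definite": 3}
ROUTE_PRIORITY = {"tier12": 0, "other_snv": 1, "cnv": 2, "str": 3, "mtdna": 4}
ACMG_STRENGTH = {"pathogenic": 2, "likely_pathogenic": 1, "vus": 0}


def label_mitochondrial(genes: Iterable[str], mito_genes: set[str]) -> bool:
    """True iff any gene is mtDNA-encoded (MT-*) or on the curated list."""
    return any(g.startswith("MT-") or g in mito_genes for g in genes)


def _adjust_confidence(base: str, steps: int) -> str:
    rank = max(1, min(3, CONFIDENCE_RANK[base] + steps))
    return {v: k for k, v in CONFIDENCE_RANK.items()}[rank]


def _base_confidence(classes: list[str], inheritance: str) -> str:
    """Evidence-derived confidence before any clinical-review adjustment.

    definite: every contributing variant pathogenic or likely
    pathogenic; probable: a biallelic pair with one P/LP and one VUS;
    possible: any remaining VUS-backed configuration.
    """
    plp = {"pathogenic", "likely_pathogenic"}
    if all(c in plp for c in classes):
        return "definite"
    if (
        inheritance == "biallelic"
        and any(c in plp for c in classes)
        and any(c == "vus" for c in classes)
    ):
        return "probable"
    return "possible"


def _in_trans(
    v1: NuclearVariant, v2: NuclearVariant, bundle: FamilyBundle
) -> Optional[bool]:
    """Phase two heterozygous variants from parental genotypes.

    Returns True (in trans), False (in cis), or None when phase cannot
    be established (a parent missing or not carrying informatively).
    """
    proband = bundle.proband
    father = bundle.member(proband.father_id)
    mother = bundle.member(proband.mother_id)
    if father is None or mother is None:
        return None

    def carrier(v: NuclearVariant, m: FamilyMember) -> Optional[bool]:
        gt = v.genotypes.get(m.sample_id, "missing")
        if gt == "missing":
            return None
        return gt in {"het", "hom_alt", "hemi"}

    c = {(i, p.sample_id): carrier(v, p) for i, v in enumerate((v1, v2)) for p in (father, mother)}
    if any(x is None for x in c.values()):
        return None
    f1, m1 = c[(0, father.sample_id)], c[(0, mother.sample_id)]
    f2, m2 = c[(1, father.sample_id)], c[(1, mother.sample_id)]
    # in trans: one variant from each parent
    if (f1 and m2 and not m1 and not f2) or (m1 and f2 and not f1 and not m2):
        return True
    # in cis: both inherited from the same single parent
    if (f1 and f2 and not m1 and not m2) or (m1 and m2 and not f1 and not f2):
        return False
    return None


def _nuclear_inheritance(
    variants: list[NuclearVariant], bundle: FamilyBundle, qc: DeNovoQc
) -> tuple[Optional[str], bool, list[NuclearVariant]]:
    """Derive (inheritance, de_novo, retained variants) for one gene.

    Returns inheritance ``None`` when the configuration is
    contradictory (e.g. a claimed biallelic pair phased in cis), in
    which case the candidate is rejected.
    """
    proband = bundle.proband
    pid = proband.sample_id
    carried = [v for v in variants if v.carried_by(pid)]
    if not carried:
        return None, False, []
    homs = [v for v in carried if v.genotypes.get(pid) == "hom_alt"]
    hets = [v for v in carried if v.genotypes.get(pid) == "het"]
    hemis = [v for v in carried if v.genotypes.get(pid) == "hemi"]

    if homs:
        return "biallelic", False, homs
    if len(hets) >= 2:
        phase = _in_trans(hets[0], hets[1], bundle)
        if phase is False:
            log.info(
                "family %s: biallelic candidate in %s rejected, variants in cis",
                bundle.family_id,
                hets[0].gene,
            )
            return None, False, []
        return "biallelic", False, hets[:2]
    single = (hets + hemis)[0]
    de_novo = detect_de_novo(single, bundle, qc)
    on_x = single.chrom in {"X", "chrX"}
    if on_x:
        if single.genotypes.get(pid) == "hemi":
            return "x_linked_recessive", de_novo, [single]
        if de_novo:
            return "x_linked_dominant", True, [single]
        return "x_linked_dominant", False, [single]
    if de_novo:
        return "monoallelic_de_novo", True, [single]
    for parent_id in (proband.father_id, proband.mother_id):
        parent = bundle.member(parent_id)
        if parent is not None and parent.affected and single.carried_by(parent.sample_id):
            return "monoallelic_AD", False, [single]
    return "monoallelic_unknown", False, [single]


def _cnv_inheritance(ann: AnnotatedCnv, bundle: FamilyBundle) -> tuple[str, bool]:
    call = ann.call
    if call.copy_number == 0:
        return "biallelic", False
    proband = bundle.proband
    father = bundle.member(proband.father_id)
    mother = bundle.member(proband.mother_id)
    parent_keys = {
        c.key
        for c in bundle.cnv_calls
        if c.sample_id in {p.sample_id for p in (father, mother) if p is not None}
        and (c.chrom, c.start, c.end, c.type) == (call.chrom, call.start, call.end, call.type)
    }
    for parent in (father, mother):
        if parent is None:
            continue
        carries = any(
            c.sample_id == parent.sample_id
            and (c.chrom, c.start, c.end, c.type) == (call.chrom, call.start, call.end, call.type)
            for c in bundle.cnv_calls
        )
        if carries and parent.affected:
            return "monoallelic_AD", False
    if father is not None and mother is not None and not parent_keys:
        return "monoallelic_de_novo", True
    return "monoallelic_unknown", False


def aggregate_family(
    bundle: FamilyBundle,
    tier_assignments: list[TierAssignment],
    channel_hits: list[CandidateChannelHit],
    cnvs: list[AnnotatedCnv],
    str_results: list[StrResult],
    mtdna_findings,
    curated: CuratedLists,
    de_novo_qc: DeNovoQc | None = None,
) -> list[CandidateDiagnosis]:
    """Build the family's candidate diagnoses from all channel outputs.

    Only reviewed variants participate: a variant with no ACMG evidence
    record was never classified and cannot support a diagnosis (the
    review step is an input to this pipeline, as it was a manual step in
    the source workflow).  Benign and likely benign variants are
    excluded.
    """
    qc = de_novo_qc or DeNovoQc()
    classes = classify_evidence_map(bundle.evidence)
    reviewed = {k for k, c in classes.items() if c in ACMG_STRENGTH}

    tiers_by_key = {t.variant.key: t for t in tier_assignments}
    diagnoses: list[CandidateDiagnosis] = []

    # --- nuclear SNV/indel candidates, grouped by gene -------------------
    gene_channels: dict[str, set[str]] = {}
    gene_variants: dict[str, dict[str, NuclearVariant]] = {}
    for hit in channel_hits:
        v = hit.variant
        if v.key not in reviewed:
            continue
        gene_channels.setdefault(v.gene, set()).add(
            "tier12" if hit.channel == "tier12" else "other_snv"
        )
        gene_variants.setdefault(v.gene, {})[v.key] = v
    # partner rule: reviewed rare variants in an already-hit gene join the
    # candidate even if no channel flagged them individually
    for v in bundle.nuclear_variants:
        if v.gene in gene_channels and v.key in reviewed and v.filter_pass:
            gene_variants[v.gene].setdefault(v.key, v)

    for gene in sorted(gene_channels):
        variants = sorted(gene_variants[gene].values(), key=lambda v: (v.chrom, v.pos, v.alt))
        inheritance, de_novo, retained = _nuclear_inheritance(variants, bundle, qc)
        if inheritance is None or not retained:
            continue
        vclasses = [classes[v.key] for v in retained]
        flags = bundle.review.get(gene, ReviewFlags())
        if flags.fit == "none":
            log.info("family %s: %s rejected by clinical fit", bundle.family_id, gene)
            continue
        confidence = _adjust_confidence(_base_confidence(vclasses, inheritance), flags.adjustment)
        route = "tier12" if "tier12" in gene_channels[gene] else "other_snv"
        diagnoses.append(
            CandidateDiagnosis(
                family_id=bundle.family_id,
                genes=[gene],
                variants=[v.key for v in retained],
                acmg_classes=vclasses,
                inheritance=inheritance,
                confidence=confidence,
                contribution=flags.contribution,
                route=route,
                is_mitochondrial=label_mitochondrial([gene], curated.mito_genes),
                de_novo=de_novo,
            )
        )

    # --- CNV candidates --------------------------------------------------
    for ann in cnvs:
        if ann.call.sample_id != bundle.proband.sample_id:
            continue
        key = ann.call.key
        if key not in reviewed:
            continue
        genes = ann.genes
        flags = bundle.review.get(genes[0], ReviewFlags())
        if flags.fit == "none":
            continue
        inheritance, de_novo = _cnv_inheritance(ann, bundle)
        confidence = _adjust_confidence(
            _base_confidence([classes[key]], inheritance), flags.adjustment
        )
        diagnoses.append(
            CandidateDiagnosis(
                family_id=bundle.family_id,
                genes=genes,
                variants=[key],
                acmg_classes=[classes[key]],
                inheritance=inheritance,
                confidence=confidence,
                contribution=flags.contribution,
                route="cnv",
                is_mitochondrial=label_mitochondrial(genes, curated.mito_genes),
                de_novo=de_novo,
            )
        )

    # --- STR candidates --------------------------------------------------
    for res in str_results:
        if not res.causative or res.genotype.sample_id != bundle.proband.sample_id:
            continue
        key = res.genotype.key
        if key not in reviewed:
            continue
        gene = res.genotype.locus
        flags = bundle.review.get(gene, ReviewFlags())
        if flags.fit == "none":
            continue
        confidence = _adjust_confidence(
            _base_confidence([classes[key]], "monoallelic_unknown"), flags.adjustment
        )
        diagnoses.append(
            CandidateDiagnosis(
                family_id=bundle.family_id,
                genes=[gene],
                variants=[key],
                acmg_classes=[classes[key]],
                inheritance="monoallelic_unknown",
                confidence=confidence,
                contribution=flags.contribution,
                route="str",
                is_mitochondrial=label_mitochondrial([gene], curated.mito_genes),
            )
        )

    # --- mtDNA candidates ------------------------------------------------
    for finding in mtdna_findings:
        key = finding.call.key
        if key not in reviewed:
            continue
        flags = bundle.review.get(finding.gene, ReviewFlags())
        if flags.fit == "none":
            continue
        inheritance = f"mtdna_{finding.inheritance}"
        confidence = _adjust_confidence(
            _base_confidence([classes[key]], inheritance), flags.adjustment
        )
        diagnoses.append(
            CandidateDiagnosis(
                family_id=bundle.family_id,
                genes=[finding.gene],
                variants=[key],
                acmg_classes=[classes[key]],
                inheritance=inheritance,
                confidence=confidence,
                contribution=flags.contribution,
                route="mtdna",
                is_mitochondrial=True,
                de_novo=finding.inheritance == "de_novo",
            )
        )

    diagnoses.sort(key=lambda d: (-CONFIDENCE_RANK[d.confidence], ROUTE_PRIORITY[d.route], d.genes))
    return diagnoses


def analyse_bundle(
    bundle: FamilyBundle,
    panels: dict[str, Panel],
    curated: CuratedLists,
    exon_models=None,
    rarity: RarityConfig | None = None,
    de_novo_qc: DeNovoQc | None = None,
    mtdna_qc: MtdnaQcConfig | None = None,
    build: str = "GRCh38",
) -> list[CandidateDiagnosis]:
    """Run every analysis stage for one family and aggregate.

    Stage order mirrors the analysis workflow: nuclear tiering and the
    candidate channels, then mtDNA, CNV and STR triage, then ACMG
    classification and aggregation.
    """
    bundle.validate()
    applied = [panels[pid] for pid in bundle.applied_panel_ids]
    assignments = tier_family(bundle, applied, rarity, de_novo_qc)

    hits: list[CandidateChannelHit] = []
    for t in assignments:
        if t.tier <= 2:
            hits.append(CandidateChannelHit(t.variant, "tier12"))
    tier13 = [t.variant for t in assignments if t.tier <= 3]
    hits.extend(clinvar_intersect(tier13, curated, build))
    by_key = {v.key: v for v in tier13}
    hits.extend(external_rank_top10(bundle.external_ranks, by_key))
    for key in sorted(bundle.gmc_variant_keys):
        if key in by_key:
            hits.append(CandidateChannelHit(by_key[key], "gmc_feedback"))

    proband = bundle.proband
    mother = bundle.member(proband.mother_id)
    # a mother present in the family was sequenced: no recorded calls
    # means the allele is absent, not that the sample is missing
    mother_calls = bundle.mtdna_calls.get(mother.sample_id, []) if mother is not None else None
    findings = analyse_mtdna(
        bundle.mtdna_calls.get(proband.sample_id, []), mother_calls, curated, mtdna_qc
    )

    cnvs = filter_cnvs(bundle.cnv_calls, exon_models or [], applied)
    strs = classify_str_table(bundle.str_genotypes, curated.str_loci, proband.age_at_enrolment)

    return aggregate_family(
        bundle, assignments, hits, cnvs, strs, findings, curated, de_novo_qc
    )


def best_diagnosis(diagnoses: list[CandidateDiagnosis]) -> Optional[CandidateDiagnosis]:
    """The family's single best diagnosis (already sorted by aggregate_family)."""
    return diagnoses[0] if diagnoses else None


def _structure(members: list[FamilyMember]) -> str:
    n = len(members)
    if n == 1:
        return "singleton"
    if n == 2:
        return "duo"
    proband = next((m for m in members if m.is_proband), members[0])
    has_both = proband.father_id is not None and proband.mother_id is not None
    if n in (3, 4) and has_both:
        return "trio_quad"
    return "other"


def summarise_cohort(
    results: dict[str, list[CandidateDiagnosis]],
    families: dict[str, list[FamilyMember]],
) -> CohortSummary:
    """Family-level cohort summary.

    Each family counts once by its best diagnosis; dual-diagnosis
    families (two retained disorders) still count once in the yield.
    ``distinct_genes`` is the union over all diagnoses, including every
    gene of multi-gene (contiguous CNV) diagnoses.
    """
    n_families = len(families)
    best = {fid: best_diagnosis(ds) for fid, ds in results.items()}
    diagnosed = {fid: b for fid, b in best.items() if b is not None}

    counts = {"definite": 0, "probable": 0, "possible": 0}
    route_counts = {r: 0 for r in ROUTE_PRIORITY}
    n_partial = n_mito = n_dual = 0
    genes: set[str] = set()
    for fid, b in diagnosed.items():
        counts[b.confidence] += 1
        route_counts[b.route] += 1
        if b.contribution == "partial":
            n_partial += 1
        if b.is_mitochondrial:
            n_mito += 1
        if len(results[fid]) > 1:
            n_dual += 1
        for d in results[fid]:
            genes.update(d.genes)

    yield_by_stratum: dict[str, tuple[int, int]] = {}
    for fid, members in families.items():
        proband = next((m for m in members if m.is_proband), members[0])
        hit = fid in diagnosed
        strata = [f"structure:{_structure(members)}"]
        if proband.age_at_enrolment is not None:
            strata.append("age:<=18" if proband.age_at_enrolment <= 18 else "age:>18")
        for s in strata:
            k, n = yield_by_stratum.get(s, (0, 0))
            yield_by_stratum[s] = (k + int(hit), n + 1)

    breakdown: dict[str, dict[str, int]] = {"nuclear_mito": {}, "non_mito": {}}
    for b in diagnosed.values():
        if b.is_mitochondrial and b.route == "mtdna":
            continue
        group = "nuclear_mito" if b.is_mitochondrial else "non_mito"
        if b.inheritance == "biallelic":
            pat = "recessive"
        elif b.de_novo:
            pat = "de_novo"
        elif b.inheritance == "monoallelic_AD":
            pat = "dominant"
        elif b.inheritance.startswith("x_linked"):
            pat = "x_linked"
        else:
            pat = "unknown"
        breakdown[group][pat] = breakdown[group].get(pat, 0) + 1

    return CohortSummary(
        n_families=n_families,
        n_diagnosed=len(diagnosed),
        n_definite=counts["definite"],
        n_probable=counts["probable"],
        n_possible=counts["possible"],
        n_partial=n_partial,
        n_mito=n_mito,
        n_non_mito=len(diagnosed) - n_mito,
        route_counts=route_counts,
        distinct_genes=len(genes),
        n_dual=n_dual,
        yield_by_stratum=yield_by_stratum,
        inheritance_breakdown=breakdown,
    )


def compare_strata(k1: int, n1: int, k2: int, n2: int) -> tuple[float, float, float]:
    """Two-sided exact test comparing diagnostic yield between two strata.

    Returns ``(p_value, proportion1, proportion2)`` from the exact
    hypergeometric (Fisher) test on the 2x2 table.  A zero margin is an
    error (the test is undefined).
    """
    table = [[k1, n1 - k1], [k2, n2 - k2]]
    margins = [k1 + k2, (n1 - k1) + (n2 - k2), n1, n2]
    if any(m == 0 for m in margins):
        raise ValueError("2x2 table has a zero margin; exact test undefined")
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return float(p), k1 / n1, k2 / n2
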