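"""Synthetic cohorts: the published-tables fixture and random generated cohorts.

The cohort under study is controlled-access, so everything here is
synthesised: :func:`build_tables_fixture` deterministically re-creates
the 104 published diagnosed families (plus 215 undiagnosed filler
families) from the transcription in :mod:`mitodx.fixture_tables`, and
:func:`generate_cohort` draws random cohorts with planted diagnoses of
every analysis route so the full pipeline can be exercised end to end
with no download.

Planted variant records are engineered to satisfy exactly their route's
rules (e.g. a trio de novo missense in a panel gene for tier 1, a
biallelic P+VUS pair for a probable diagnosis, an mtDNA list variant at
a drawn heteroplasmy above 1%); undiagnosed families carry only
background variation — common panel-gene alleles, rare off-panel
variants, sub-threshold mtDNA noise — that the pipeline must reject.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import networkx as nx
import numpy as np
import pandas as pd

from . import io as mio
from .fixture_tables import (
    ALL_ROWS,
    CLINVAR_ROUTE,
    DE_NOVO_CODES,
    EXOMISER_ROUTE,
    INHERITANCE_LABEL,
    MITO_NUCLEAR_GENES,
    N_FAMILIES,
    REVIEW_ADJUSTMENT,
    X_GENES,
)
from .types import (
    CnvCall,
    CuratedLists,
    ExonModel,
    FamilyBundle,
    FamilyMember,
    MdcConfig,
    MtdnaCall,
    NuclearVariant,
    Panel,
    PhenotypePacket,
    ReviewFlags,
    StrGenotype,
)

EVIDENCE_FOR_CLASS = {
    "P": [("PVS1", None), ("PS3", None)],
    "LP": [("PS3", None), ("PM2", None)],
    "VUS": [("PM2", None)],
}


@dataclass
class Cohort:
    """An in-memory cohort: family bundles plus the shared reference inputs."""

    bundles: dict[str, FamilyBundle]
    panels: dict[str, Panel]
    curated: CuratedLists
    exon_models: list[ExonModel]
    expected: pd.DataFrame  # per-family expected diagnosis labels (may be empty)
    ontology: Optional[nx.MultiDiGraph] = None


@dataclass
class CohortSpec:
    """Shape and planting rates for a generated cohort.

    Defaults emulate the study conditions: 319 families in the
    recruited structure mix (singletons and trios dominate), 41% of
    probands children, and diagnoses planted at the published route
    mix (104/319 families overall).
    """

    n_families: int = 319
    structure_mix: dict[str, float] = field(
        default_factory=lambda: {"singleton": 0.32, "duo": 0.13, "trio": 0.46, "quad": 0.09}
    )
    child_fraction: float = 0.41
    planted_rates: dict[str, float] = field(
        default_factory=lambda: {
            "tier12": 69 / 319,
            "other_snv": 18 / 319,
            "cnv": 8 / 319,
            "str": 3 / 319,
            "mtdna": 6 / 319,
        }
    )
    background_variants_per_family: int = 4
    phenotype_terms_mean: float = 7.0
    seed: int = 0

    def validate(self) -> None:
        if abs(sum(self.structure_mix.values()) - 1.0) > 1e-9:
            raise ValueError("structure_mix proportions must sum to 1")
        if sum(self.planted_rates.values()) > 1.0 + 1e-9:
            raise ValueError("planted rates sum above 1")


# ---------------------------------------------------------------------------
# deterministic coordinates for synthesised variants


def _stable_hash(text: str) -> int:
    h = 0
    for ch in text:
        h = (h * 131 + ord(ch)) % 1_000_003
    return h


#: genes that must sit adjacently on one chromosome (contiguous cluster,
#: hit by a single CNV)
_PLACEMENT_OVERRIDES = {"ATAD3A": ("1", 1_440_000), "ATAD3B": ("1", 1_447_000)}


def gene_chrom(gene: str) -> str:
    if gene in _PLACEMENT_OVERRIDES:
        return _PLACEMENT_OVERRIDES[gene][0]
    if gene in X_GENES:
        return "X"
    return str(1 + _stable_hash(gene) % 22)


def gene_base_pos(gene: str) -> int:
    if gene in _PLACEMENT_OVERRIDES:
        return _PLACEMENT_OVERRIDES[gene][1]
    return 1_000_000 + _stable_hash(gene) * 97


def make_snv(
    gene: str,
    index: int,
    consequence: str,
    genotypes: dict[str, str],
    af: float = 0.0,
    depth: int = 30,
    gq: int = 99,
    filter_pass: bool = True,
    salt: int = 0,
) -> NuclearVariant:
    """Synthesise one deterministic variant record for ``gene``.

    ``salt`` (typically the family number) keeps coordinates distinct
    when several families carry variants in the same gene.
    """
    ref, alt = ("A", "G") if index % 2 == 0 else ("C", "T")
    return NuclearVariant(
        chrom=gene_chrom(gene),
        pos=gene_base_pos(gene) + salt * 997 + index * 7,
        ref=ref,
        alt=alt,
        gene=gene,
        consequence=consequence,
        population_af=af,
        genotypes=dict(genotypes),
        depth={s: depth for s in genotypes},
        gq={s: gq for s in genotypes},
        filter_pass=filter_pass,
    )


def _mt_call(sample: str, pos: int, ref: str, alt: str, af: float, depth: int = 2000) -> MtdnaCall:
    per_strand = max(1, round(depth * af / 200.0)) if af > 0 else 0
    per_strand = min(per_strand, depth // 2)
    return MtdnaCall(
        position=pos,
        ref=ref,
        alt=alt,
        allele_fraction=af,
        depth=depth,
        forward_alt_reads=per_strand,
        reverse_alt_reads=per_strand,
        sample_id=sample,
    )


# ---------------------------------------------------------------------------
# family scaffolding


def _members_for(code: str, fid: str, age: int, sex: str) -> list[FamilyMember]:
    """Minimal family structure consistent with an inheritance code."""
    sex_full = {"M": "male", "F": "female"}[sex]
    proband = FamilyMember(fid, f"{fid}_P", None, None, sex_full, True, age, True)
    trio_codes = {"comphet", "de_novo", "xlr_dn", "xld_dn", "cnv_dn"}
    if code in trio_codes:
        proband.father_id, proband.mother_id = f"{fid}_FA", f"{fid}_MO"
        return [
            proband,
            FamilyMember(fid, f"{fid}_FA", None, None, "male", False, age + 30),
            FamilyMember(fid, f"{fid}_MO", None, None, "female", False, age + 28),
        ]
    if code in {"ad", "cnv_ad"}:  # affected carrier mother
        proband.mother_id = f"{fid}_MO"
        return [proband, FamilyMember(fid, f"{fid}_MO", None, None, "female", True, age + 28)]
    if code in {"xlr_mat", "mt_vlow", "mt_dn", "mt_mat"}:  # unaffected mother
        proband.mother_id = f"{fid}_MO"
        return [proband, FamilyMember(fid, f"{fid}_MO", None, None, "female", False, age + 28)]
    if code == "presumed":  # affected sibling, parents unavailable
        sib_sex = "female" if sex_full == "male" else "male"
        return [proband, FamilyMember(fid, f"{fid}_S1", None, None, sib_sex, True, max(0, age - 2))]
    return [proband]


def _snv_genotypes(code: str, fid: str, index: int, on_x: bool, male: bool) -> dict[str, str]:
    p, fa, mo, s1 = f"{fid}_P", f"{fid}_FA", f"{fid}_MO", f"{fid}_S1"
    carrier = "hemi" if on_x and male else "het"
    if code == "comphet":
        if index == 0:
            return {p: "het", fa: "het", mo: "hom_ref"}
        return {p: "het", fa: "hom_ref", mo: "het"}
    if code == "hom":
        return {p: "hom_alt"}
    if code == "presumed":
        return {p: "het", s1: "het"}
    if code in {"de_novo", "xld_dn"}:
        return {p: carrier if code != "xld_dn" else "het", fa: "hom_ref", mo: "hom_ref"}
    if code == "xlr_dn":
        return {p: "hemi", fa: "hom_ref", mo: "hom_ref"}
    if code == "xlr_mat":
        return {p: "hemi", mo: "het"}
    if code == "ad":
        return {p: "het", mo: "het"}
    if code == "mono_unknown":
        return {p: carrier}
    raise ValueError(f"unknown inheritance code {code!r}")


def _exon_model_for(gene: str) -> ExonModel:
    chrom, base = gene_chrom(gene), gene_base_pos(gene)
    return ExonModel(gene=gene, exons=[(chrom, base + i * 2000, base + i * 2000 + 200) for i in range(3)])


# ---------------------------------------------------------------------------
# the published-tables fixture


def build_tables_fixture() -> Cohort:
    """Re-create the published diagnosis tables as a runnable cohort.

    Returns 319 families: the 104 diagnosed families transcribed from
    the published tables plus 215 undiagnosed filler families, with the
    panels, curated lists and exon models the pipeline needs, and an
    expected-results table carrying the printed confidence,
    contribution, inheritance and route labels.  The build is pure:
    identical output on every call.
    """
    bundles: dict[str, FamilyBundle] = {}
    expected_rows = []
    clinvar: set[tuple[str, int, str, str]] = set()
    exon_models: dict[str, ExonModel] = {}
    panel_genes_other: set[str] = set()

    for row in ALL_ROWS:
        num, age, sex, contribution, confidence, entries = row
        fid = f"F{num:03d}"
        code0 = entries[0][2]
        members = _members_for(code0, fid, age, sex)
        bundle = FamilyBundle(family_id=fid, members=members)
        bundles[fid] = bundle
        p_sid = f"{fid}_P"
        male = sex == "M"
        genes_all: list[str] = []
        route = None

        for gene_spec, kind, code, payload in entries:
            genes = gene_spec if isinstance(gene_spec, list) else [gene_spec]
            genes_all.extend(genes)
            for g in genes:
                bundle.review[g] = ReviewFlags(
                    fit="full",
                    contribution=contribution,
                    adjustment=REVIEW_ADJUSTMENT.get(num, 0),
                )
            if kind == "snv":
                gene = genes[0]
                on_x = gene in X_GENES
                for i, (consequence, acmg) in enumerate(payload):
                    v = make_snv(gene, i, consequence, _snv_genotypes(code, fid, i, on_x, male), salt=num)
                    bundle.nuclear_variants.append(v)
                    bundle.evidence[v.key] = EVIDENCE_FOR_CLASS[acmg]
                    if num in CLINVAR_ROUTE:
                        clinvar.add((v.chrom, v.pos, v.ref, v.alt))
                    if num in EXOMISER_ROUTE:
                        bundle.external_ranks.append((v.key, i + 1))
                route = route or ("other_snv" if num in CLINVAR_ROUTE | EXOMISER_ROUTE else "tier12")
                if num not in CLINVAR_ROUTE | EXOMISER_ROUTE and num >= 40:
                    panel_genes_other.add(gene)
            elif kind == "cnv":
                cnv_type, cn, acmg = payload
                for g in genes:
                    exon_models.setdefault(g, _exon_model_for(g))
                    if num >= 40:
                        panel_genes_other.add(g)
                chroms = {gene_chrom(g) for g in genes}
                chrom = sorted(chroms)[0]
                start = min(gene_base_pos(g) for g in genes)
                end = max(gene_base_pos(g) + 4400 for g in genes)
                call = CnvCall(chrom, start, end, cnv_type, True, p_sid, copy_number=cn)
                bundle.cnv_calls.append(call)
                bundle.evidence[call.key] = EVIDENCE_FOR_CLASS[acmg]
                if code == "cnv_dn":
                    pass  # parents carry no call
                if code == "cnv_ad":
                    bundle.cnv_calls.append(
                        CnvCall(chrom, start, end, cnv_type, True, f"{fid}_MO", copy_number=cn)
                    )
                route = route or "cnv"
            elif kind == "str":
                locus, a1, a2, acmg = payload
                g = StrGenotype(p_sid, locus, a1, a2, visual_review="confirmed")
                bundle.str_genotypes.append(g)
                bundle.evidence[g.key] = EVIDENCE_FOR_CLASS[acmg]
                route = route or "str"
            elif kind == "mtdna":
                pos, ref, alt, af, mother_af, acmg = payload
                call = _mt_call(p_sid, pos, ref, alt, af)
                bundle.mtdna_calls[p_sid] = [call]
                bundle.evidence[call.key] = EVIDENCE_FOR_CLASS[acmg]
                if mother_af is not None:
                    mo_sid = f"{fid}_MO"
                    bundle.mtdna_calls[mo_sid] = (
                        [_mt_call(mo_sid, pos, ref, alt, mother_af)] if mother_af > 0 else []
                    )
                route = route or "mtdna"

        expected_rows.append(
            {
                "family_id": fid,
                "age": age,
                "sex": sex,
                "confidence": confidence,
                "contribution": contribution,
                "inheritance": INHERITANCE_LABEL[entries[0][2]],
                "de_novo": entries[0][2] in DE_NOVO_CODES,
                "route": route,
                "genes": ";".join(sorted(genes_all)),
                "mitochondrial": num <= 39,
            }
        )

    # 215 undiagnosed filler families with background variation only
    panel_gene_cycle = sorted(MITO_NUCLEAR_GENES)
    for num in range(105, N_FAMILIES + 1):
        fid = f"F{num:03d}"
        age = (num * 3) % 90
        sex = "M" if num % 2 else "F"
        members = _members_for("mono_unknown", fid, age, sex)
        bundle = FamilyBundle(family_id=fid, members=members)
        bundles[fid] = bundle
        p_sid = f"{fid}_P"
        common_gene = panel_gene_cycle[num % len(panel_gene_cycle)]
        bundle.nuclear_variants.append(
            make_snv(common_gene, 3 + num % 2, "missense", {p_sid: "het"}, af=0.05, salt=num)
        )
        bundle.nuclear_variants.append(
            make_snv(f"FILLERG{num % 40}", 0, "intronic", {p_sid: "het"}, af=0.0, salt=num)
        )
        if num == 105:  # sub-threshold spike-in of a listed variant: must be rejected
            bundle.mtdna_calls[p_sid] = [_mt_call(p_sid, 3243, "A", "G", 0.5)]
        elif num == 106:  # strand-imbalanced artefact of a listed variant
            bundle.mtdna_calls[p_sid] = [
                MtdnaCall(8344, "A", "G", 30.0, 2000, 600, 0, p_sid)
            ]
        elif num % 5 == 0:  # benign private mtDNA variation, not on the list
            bundle.mtdna_calls[p_sid] = [_mt_call(p_sid, 5000 + num % 100, "A", "G", 5.0)]
        if 107 <= num <= 116:
            loci = mio.read_str_loci(mio.default_data_path("str_loci.tsv"))
            bundle.str_genotypes = [
                StrGenotype(p_sid, locus, 15, 16) for locus in sorted(loci)
            ]

    panels = {
        "mito": Panel("mito", "Mitochondrial disorders", {g: "green" for g in sorted(MITO_NUCLEAR_GENES)}),
        "other": Panel(
            "other",
            "Phenotype-driven disorders",
            {g: "green" for g in sorted(panel_genes_other)},
        ),
    }
    for b in bundles.values():
        b.applied_panel_ids = ["mito", "other"]

    curated = CuratedLists(
        pathogenic_mtdna=mio.read_pathogenic_mtdna(mio.default_data_path("pathogenic_mtdna.tsv")),
        clinvar_plp=clinvar,
        clinvar_build="GRCh38",
        mito_genes=set(MITO_NUCLEAR_GENES),
        str_loci=mio.read_str_loci(mio.default_data_path("str_loci.tsv")),
    )
    expected = pd.DataFrame(expected_rows).set_index("family_id")
    return Cohort(
        bundles=bundles,
        panels=panels,
        curated=curated,
        exon_models=sorted(exon_models.values(), key=lambda m: m.gene),
        expected=expected,
    )


# ---------------------------------------------------------------------------
# synthetic ontology (an HPO-style stand-in; the real ontology is not shipped)

SYSTEMS = [
    ("HP:0000707", "Abnormality of the nervous system"),
    ("HP:0033127", "Abnormality of the musculoskeletal system"),
    ("HP:0001939", "Abnormality of metabolism/homeostasis"),
    ("HP:0000478", "Abnormality of the eye"),
    ("HP:0001626", "Abnormality of the cardiovascular system"),
    ("HP:0000598", "Abnormality of the ear"),
    ("HP:0000818", "Abnormality of the endocrine system"),
    ("HP:0025031", "Abnormality of the digestive system"),
    ("HP:0002086", "Abnormality of the respiratory system"),
    ("HP:0002715", "Abnormality of the immune system"),
    ("HP:0000119", "Abnormality of the genitourinary system"),
    ("HP:0001507", "Growth abnormality"),
    ("HP:0001574", "Abnormality of the integument"),
    ("HP:0001871", "Abnormality of blood and blood-forming tissues"),
    ("HP:0000152", "Abnormality of head or neck"),
]

_MID_TERMS = {
    "HP:0003011": ("Abnormality of the musculature", ["HP:0033127"]),
    "HP:0011804": ("Abnormal muscle physiology", ["HP:0003011"]),
    "HP:0012638": ("Abnormal nervous system physiology", ["HP:0000707"]),
    "HP:0012639": ("Abnormal nervous system morphology", ["HP:0000707"]),
    "HP:0011442": ("Abnormal central motor function", ["HP:0012638"]),
}

_LEAF_TERMS = {
    "HP:0003198": ("Myopathy", ["HP:0011804"]),
    "HP:0001324": ("Muscle weakness", ["HP:0011804"]),
    "HP:0000602": ("Ophthalmoplegia", ["HP:0000478", "HP:0011442"]),
    "HP:0003546": ("Exercise intolerance", ["HP:0011804"]),
    "HP:0000508": ("Ptosis", ["HP:0000478", "HP:0003011"]),
    "HP:0001250": ("Seizure", ["HP:0012638"]),
    "HP:0002401": ("Stroke-like episode", ["HP:0012638"]),
    "HP:0002376": ("Developmental regression", ["HP:0012638"]),
    "HP:0001251": ("Ataxia", ["HP:0011442"]),
    "HP:0001257": ("Spasticity", ["HP:0011442"]),
    "HP:0001249": ("Intellectual disability", ["HP:0012638"]),
    "HP:0000365": ("Hearing impairment", ["HP:0000598", "HP:0000707"]),
    "HP:0001639": ("Hypertrophic cardiomyopathy", ["HP:0001626"]),
    "HP:0000819": ("Diabetes mellitus", ["HP:0000818", "HP:0001939"]),
    "HP:0004322": ("Short stature", ["HP:0001507"]),
    "HP:0000556": ("Retinopathy", ["HP:0000478"]),
    "HP:0000505": ("Visual impairment", ["HP:0000478"]),
    "HP:0002013": ("Vomiting", ["HP:0025031"]),
    "HP:0003128": ("Lactic acidosis", ["HP:0001939"]),
    "HP:0002490": ("Increased CSF lactate", ["HP:0001939", "HP:0000707"]),
    "HP:0002151": ("Increased serum lactate", ["HP:0001939"]),
    "HP:0002134": ("Abnormality of the basal ganglia", ["HP:0012639"]),
    "HP:0001987": ("Hyperammonemia", ["HP:0001939"]),
    "HP:0003200": ("Ragged-red muscle fibers", ["HP:0003011"]),
    "HP:0003688": ("Decreased cytochrome-c oxidase in muscle", ["HP:0003011", "HP:0001939"]),
    "HP:0011923": ("Decreased activity of mitochondrial complex I", ["HP:0001939"]),
    "HP:0008347": ("Decreased activity of mitochondrial complex IV", ["HP:0001939"]),
    "HP:0000952": ("Jaundice", ["HP:0025031"]),
    "HP:0002090": ("Pneumonia", ["HP:0002086", "HP:0002715"]),
    "HP:0001903": ("Anemia", ["HP:0001871"]),
    "HP:0000083": ("Renal insufficiency", ["HP:0000119"]),
    "HP:0000962": ("Hyperkeratosis", ["HP:0001574"]),
    "HP:0000218": ("High palate", ["HP:0000152"]),
}


def build_ontology() -> nx.MultiDiGraph:
    """A small synthetic HPO-style ontology as an obonet-compatible graph.

    Real top-level system identifiers, synthetic depth.  ``is_a`` edges
    point from child to parent, matching obonet's convention.
    """
    g = nx.MultiDiGraph()
    g.add_node("HP:0000001", name="All")
    g.add_node("HP:0000118", name="Phenotypic abnormality")
    g.add_edge("HP:0000118", "HP:0000001", key="is_a")
    for tid, name in SYSTEMS:
        g.add_node(tid, name=name)
        g.add_edge(tid, "HP:0000118", key="is_a")
    for tid, (name, parents) in {**_MID_TERMS, **_LEAF_TERMS}.items():
        g.add_node(tid, name=name)
        for parent in parents:
            g.add_edge(tid, parent, key="is_a")
    return g


def write_obo(graph: nx.MultiDiGraph, path: str | Path) -> None:
    """Serialise the ontology in OBO format (synthetic stand-in file)."""
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\nontology: hp-synthetic\n")
        for node in sorted(graph.nodes):
            fh.write(f"\n[Term]\nid: {node}\nname: {graph.nodes[node].get('name', node)}\n")
            for _, parent, key in sorted(graph.out_edges(node, keys=True)):
                if key == "is_a":
                    fh.write(f"is_a: {parent} ! {graph.nodes[parent].get('name', parent)}\n")


def default_mdc_config() -> MdcConfig:
    """The shipped provisional item map with the standard caps."""
    return MdcConfig(
        item_map=mio.read_mdc_items(mio.default_data_path("mdc_items.tsv")),
        section_caps={s: 4 for s in
                      ("clinical_muscular", "clinical_cns", "clinical_multisystem",
                       "metabolic_imaging", "morphology")},
        clinical_group_cap=4,
        total_cap=12,
    )


# ---------------------------------------------------------------------------
# random generated cohorts with planted truth

#: per-route planting scenarios: (name, needs_trio, acmg classes, code)
_TIER12_SCENARIOS = [
    ("dn_missense", True, ["P"], "de_novo", "definite"),
    ("comphet_plp", True, ["P", "LP"], "comphet", "definite"),
    ("hom_lof", False, ["P"], "hom", "definite"),
    ("mono_p", False, ["P"], "mono_unknown", "definite"),
    ("comphet_pvus", True, ["P", "VUS"], "comphet", "probable"),
    ("dn_vus", True, ["VUS"], "de_novo", "possible"),
]
_OTHER_SNV_SCENARIOS = [
    ("hom_clinvar", False, ["P"], "hom", "definite"),
    ("mono_clinvar", False, ["P"], "mono_unknown", "definite"),
]


def generate_cohort(spec: CohortSpec | None = None, seed: int | None = None) -> tuple[Cohort, dict]:
    """Generate a random cohort with planted diagnoses and return its truth.

    Returns ``(cohort, truth)`` where ``truth`` maps family id to the
    planted ``(route, genes, confidence, inheritance)``.  Reproducible:
    the same seed yields identical output.

    Raises
    ------
    ValueError
        If the spec is infeasible (e.g. more trio-requiring plants than
        trio families).
    """
    spec = spec or CohortSpec()
    if seed is not None:
        spec = CohortSpec(**{**spec.__dict__, "seed": seed})
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    n = spec.n_families
    structures: list[str] = []
    keys = sorted(spec.structure_mix)
    counts = {k: int(spec.structure_mix[k] * n) for k in keys}
    while sum(counts.values()) < n:
        counts[keys[int(rng.integers(len(keys)))]] += 1
    for k in keys:
        structures += [k] * counts[k]
    rng.shuffle(structures)

    panel_genes = [f"SGENE{i:02d}" for i in range(1, 41)]
    off_genes = [f"OGENE{i:02d}" for i in range(1, 41)]
    str_loci = mio.read_str_loci(mio.default_data_path("str_loci.tsv"))
    dominant_loci = sorted(l for l, d in str_loci.items() if d.inheritance_mode == "dominant")
    mt_list = mio.read_pathogenic_mtdna(mio.default_data_path("pathogenic_mtdna.tsv"))
    mt_snvs = [e for e in mt_list if len(e[1]) == 1 and len(e[2]) == 1]

    bundles: dict[str, FamilyBundle] = {}
    truth: dict[str, dict] = {}
    clinvar: set[tuple[str, int, str, str]] = set()
    exon_models = {g: _exon_model_for(g) for g in panel_genes}

    # decide planted routes and match them to structurally compatible families
    plant_counts = {r: int(round(spec.planted_rates.get(r, 0.0) * n)) for r in
                    ("tier12", "other_snv", "cnv", "str", "mtdna")}
    pool_trio = [i for i, s in enumerate(structures) if s in {"trio", "quad"}]
    pool_any = list(range(n))
    rng.shuffle(pool_trio)
    plans: dict[int, tuple[str, tuple]] = {}

    def take(pool: list[int]) -> int:
        while pool:
            i = pool.pop()
            if i not in plans:
                return i
        raise ValueError("infeasible cohort spec: not enough compatible families to plant")

    for route in ("tier12", "other_snv", "cnv", "str", "mtdna"):
        for _ in range(plant_counts[route]):
            if route == "tier12":
                name, needs_trio, classes, code, conf = _TIER12_SCENARIOS[
                    int(rng.integers(len(_TIER12_SCENARIOS)))
                ]
                idx = take(pool_trio if needs_trio else pool_any)
                plans[idx] = (route, (name, classes, code, conf))
            elif route == "other_snv":
                name, _, classes, code, conf = _OTHER_SNV_SCENARIOS[
                    int(rng.integers(len(_OTHER_SNV_SCENARIOS)))
                ]
                idx = take(pool_any)
                plans[idx] = (route, (name, classes, code, conf))
            elif route == "cnv":
                kind = ["cnv_hom", "cnv_dn", "cnv_het"][int(rng.integers(3))]
                idx = take(pool_trio if kind == "cnv_dn" else pool_any)
                plans[idx] = (route, (kind,))
            elif route == "str":
                idx = take(pool_any)
                plans[idx] = (route, (dominant_loci[int(rng.integers(len(dominant_loci)))],))
            elif route == "mtdna":
                idx = take(pool_trio)  # needs a mother in the family
                plans[idx] = (route, ())

    leaves = sorted(_LEAF_TERMS)
    for i in range(n):
        fid = f"S{i + 1:03d}"
        age = int(rng.integers(0, 19)) if rng.random() < spec.child_fraction else int(rng.integers(19, 90))
        sex = "M" if rng.random() < 0.5 else "F"
        plan = plans.get(i)
        structure = structures[i]

        if plan is None:
            code = "mono_unknown" if structure == "singleton" else (
                "ad" if structure == "duo" else "de_novo"
            )
            members = _members_for(code, fid, age, sex)
            if code == "ad":  # background families: make the parent unaffected
                members[1].affected = False
            bundle = FamilyBundle(fid, members)
        else:
            route, detail = plan
            if route in {"tier12", "other_snv"}:
                code = detail[2]
            elif route == "cnv":
                code = detail[0]
            elif route == "str":
                code = "str"
            else:
                code = "mt_mat"
            members = _members_for(code, fid, age, sex)
            bundle = FamilyBundle(fid, members)
        bundles[fid] = bundle
        p_sid = f"{fid}_P"
        male = sex == "M"

        if plan is not None:
            route, detail = plan
            if route in {"tier12", "other_snv"}:
                name, classes, code, conf = detail
                gene_pool = panel_genes if route == "tier12" else off_genes
                gene = gene_pool[int(rng.integers(len(gene_pool)))]
                lof = name == "hom_lof"
                for j, acmg in enumerate(classes):
                    consequence = "nonsense" if lof else "missense"
                    v = make_snv(gene, j, consequence, _snv_genotypes(code, fid, j, False, male), salt=i)
                    bundle.nuclear_variants.append(v)
                    bundle.evidence[v.key] = EVIDENCE_FOR_CLASS[acmg]
                    if route == "other_snv":
                        clinvar.add((v.chrom, v.pos, v.ref, v.alt))
                truth[fid] = {
                    "route": route, "genes": [gene], "confidence": conf,
                    "inheritance": INHERITANCE_LABEL[code],
                }
            elif route == "cnv":
                kind = detail[0]
                gene = panel_genes[int(rng.integers(len(panel_genes)))]
                model = exon_models[gene]
                cn = 0 if kind == "cnv_hom" else 1
                call = CnvCall(model.exons[0][0], model.exons[0][1], model.exons[-1][2],
                               "loss", True, p_sid, copy_number=cn)
                bundle.cnv_calls.append(call)
                bundle.evidence[call.key] = EVIDENCE_FOR_CLASS["P"]
                truth[fid] = {
                    "route": "cnv", "genes": [gene], "confidence": "definite",
                    "inheritance": INHERITANCE_LABEL[kind],
                }
            elif route == "str":
                locus = detail[0]
                d = str_loci[locus]
                repeats = d.full_min + int(rng.integers(0, 40))
                g = StrGenotype(p_sid, locus, repeats, max(1, d.normal_max // 2), "confirmed")
                bundle.str_genotypes.append(g)
                bundle.evidence[g.key] = EVIDENCE_FOR_CLASS["P"]
                truth[fid] = {
                    "route": "str", "genes": [locus], "confidence": "definite",
                    "inheritance": "monoallelic_unknown",
                }
            else:  # mtdna
                pos, ref, alt, label, mtgene = mt_snvs[int(rng.integers(len(mt_snvs)))]
                af = float(rng.uniform(2.0, 100.0))
                bundle.mtdna_calls[p_sid] = [_mt_call(p_sid, pos, ref, alt, round(af, 1))]
                mo_sid = f"{fid}_MO"
                maternal = rng.random() < 0.5
                if maternal:
                    mo_af = round(max(1.0, af * 0.6), 1)
                    bundle.mtdna_calls[mo_sid] = [_mt_call(mo_sid, pos, ref, alt, mo_af)]
                    inh = "mtdna_maternal"
                else:
                    bundle.mtdna_calls[mo_sid] = []
                    inh = "mtdna_de_novo"
                key = bundle.mtdna_calls[p_sid][0].key
                bundle.evidence[key] = EVIDENCE_FOR_CLASS["P"]
                truth[fid] = {
                    "route": "mtdna", "genes": [mtgene], "confidence": "definite",
                    "inheritance": inh,
                }

        # background variation in every family
        sample_ids = [m.sample_id for m in bundle.members]
        planted_genes = set(truth.get(fid, {}).get("genes", []))
        n_common = int(rng.poisson(spec.background_variants_per_family))
        for j in range(n_common):
            gene = panel_genes[int(rng.integers(len(panel_genes)))]
            if gene in planted_genes:
                continue
            af = float(rng.uniform(0.02, 0.3))
            gts = {s: ("het" if rng.random() < af * 2 else "hom_ref") for s in sample_ids}
            gts[p_sid] = "het"
            bundle.nuclear_variants.append(make_snv(gene, 4 + j, "missense", gts, af=round(af, 4), salt=i))
        for j in range(int(rng.integers(1, 3))):
            gene = off_genes[int(rng.integers(len(off_genes)))]
            if gene in planted_genes:
                continue
            bundle.nuclear_variants.append(
                make_snv(gene, 4 + j, "intronic", {p_sid: "het"}, af=0.0, salt=i)
            )
        if rng.random() < 0.3:  # sub-threshold mtDNA noise at a listed site
            pos, ref, alt, _, _ = mt_snvs[int(rng.integers(len(mt_snvs)))]
            bundle.mtdna_calls.setdefault(p_sid, []).append(
                _mt_call(p_sid, pos, ref, alt, round(float(rng.uniform(0.05, 0.9)), 2))
            )
        for locus in rng.choice(sorted(str_loci), size=3, replace=False):
            if bundle.str_genotypes and any(g.locus == locus for g in bundle.str_genotypes):
                continue
            d = str_loci[locus]
            bundle.str_genotypes.append(
                StrGenotype(p_sid, locus,
                            int(rng.integers(5, max(6, d.normal_max // 2))),
                            int(rng.integers(5, max(6, d.normal_max // 2))))
            )
        k = max(1, int(rng.poisson(spec.phenotype_terms_mean)))
        terms = set(rng.choice(leaves, size=min(k, len(leaves)), replace=False))
        bundle.phenotypes[p_sid] = PhenotypePacket(p_sid, {str(t) for t in terms})

    panels = {"synthetic": Panel("synthetic", "Synthetic panel", {g: "green" for g in panel_genes})}
    for b in bundles.values():
        b.applied_panel_ids = ["synthetic"]
    curated = CuratedLists(
        pathogenic_mtdna=mt_list,
        clinvar_plp=clinvar,
        clinvar_build="GRCh38",
        mito_genes=set(),
        str_loci=str_loci,
    )
    cohort = Cohort(
        bundles=bundles,
        panels=panels,
        curated=curated,
        exon_models=sorted(exon_models.values(), key=lambda m: m.gene),
        expected=pd.DataFrame(
            [{"family_id": fid, **{k: (";".join(v) if isinstance(v, list) else v)
                                   for k, v in t.items()}} for fid, t in sorted(truth.items())]
        ),
        ontology=build_ontology(),
    )
    return cohort, truth


# ---------------------------------------------------------------------------
# on-disk serialisation of a cohort (the pipeline's input layout)


def write_cohort(cohort: Cohort, outdir: str | Path) -> None:
    """Write a cohort to the directory layout the pipeline reads.

    Layout: ``pedigree.ped``, ``families/<fid>.vcf``, ``mtdna_calls.tsv``,
    ``cnv_calls.tsv``, ``str_genotypes.tsv``, ``panels/<id>.tsv``,
    ``applied_panels.tsv``, ``exons.tsv``, ``clinvar_plp.tsv``,
    ``pathogenic_mtdna.tsv``, ``str_loci.tsv``, ``mito_genes.tsv``,
    ``evidence.tsv``, ``review.tsv``, ``ranks.tsv``, ``phenotypes.tsv``,
    ``ontology.obo`` and ``expected.tsv``.
    """
    outdir = Path(outdir)
    (outdir / "families").mkdir(parents=True, exist_ok=True)
    (outdir / "panels").mkdir(exist_ok=True)

    families = {fid: b.members for fid, b in sorted(cohort.bundles.items())}
    mio.write_pedigree(families, outdir / "pedigree.ped")
    for fid, b in sorted(cohort.bundles.items()):
        if b.nuclear_variants:
            mio.write_family_vcf(
                b.nuclear_variants, [m.sample_id for m in b.members], outdir / "families" / f"{fid}.vcf"
            )
    mt_all: dict[str, list[MtdnaCall]] = {}
    for b in cohort.bundles.values():
        for sid, calls in b.mtdna_calls.items():
            mt_all.setdefault(sid, []).extend(calls)
    mio.write_mtdna_calls(mt_all, outdir / "mtdna_calls.tsv")
    mio.write_cnv_calls(
        [c for b in cohort.bundles.values() for c in b.cnv_calls], outdir / "cnv_calls.tsv"
    )
    mio.write_str_genotypes(
        [g for b in cohort.bundles.values() for g in b.str_genotypes], outdir / "str_genotypes.tsv"
    )
    for pid, panel in sorted(cohort.panels.items()):
        mio.write_panel(panel, outdir / "panels" / f"{pid}.tsv")
    pd.DataFrame(
        [{"family_id": fid, "panel_id": pid}
         for fid, b in sorted(cohort.bundles.items()) for pid in b.applied_panel_ids],
        columns=["family_id", "panel_id"],
    ).to_csv(outdir / "applied_panels.tsv", sep="\t", index=False)
    mio.write_exon_models(cohort.exon_models, outdir / "exons.tsv")

    with open(outdir / "clinvar_plp.tsv", "w") as fh:
        fh.write(f"#build={cohort.curated.clinvar_build}\n")
        fh.write("chrom\tpos\tref\talt\tclass\n")
        for chrom, pos, ref, alt in sorted(cohort.curated.clinvar_plp):
            fh.write(f"{chrom}\t{pos}\t{ref}\t{alt}\tP/LP\n")
    pd.DataFrame(
        [{"position": p, "ref": r, "alt": a, "label": l, "gene": g}
         for p, r, a, l, g in cohort.curated.pathogenic_mtdna]
    ).to_csv(outdir / "pathogenic_mtdna.tsv", sep="\t", index=False)
    with open(mio.default_data_path("str_loci.tsv")) as src, open(outdir / "str_loci.tsv", "w") as dst:
        dst.write(src.read())
    pd.DataFrame({"gene": sorted(cohort.curated.mito_genes)}).to_csv(
        outdir / "mito_genes.tsv", sep="\t", index=False
    )

    evidence: dict[str, list] = {}
    for b in cohort.bundles.values():
        evidence.update(b.evidence)
    mio.write_evidence(evidence, outdir / "evidence.tsv")
    mio.write_review_flags(
        {fid: b.review for fid, b in sorted(cohort.bundles.items()) if b.review},
        outdir / "review.tsv",
    )
    ranks = {
        f"{fid}_P": b.external_ranks for fid, b in sorted(cohort.bundles.items()) if b.external_ranks
    }
    mio.write_external_ranks(ranks, outdir / "ranks.tsv")
    packets = {}
    for b in cohort.bundles.values():
        packets.update(b.phenotypes)
    mio.write_phenotype_packets(packets, outdir / "phenotypes.tsv")
    write_obo(cohort.ontology or build_ontology(), outdir / "ontology.obo")
    if cohort.expected is not None and len(cohort.expected):
        cohort.expected.reset_index(drop=cohort.expected.index.name is None).to_csv(
            outdir / "expected.tsv", sep="\t", index=False
        )
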