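"""Readers and writers for every external input of the pipeline.

Formats
-------
PED
    6+ whitespace-delimited columns: family, sample, father (0 =
    missing), mother, sex (1 male / 2 female / 0 unknown), phenotype
    (2 = affected).  Optional columns 7 (proband flag, 1 = proband) and
    8 (age at enrolment in years).
VCF 4.2
    Multi-sample family VCF with per-sample GT/DP/GQ; gene, consequence
    and population AF are read from configurable INFO keys (defaults
    GENE, CSQ, AF).  Multi-allelic sites are decomposed on read.
TSV
    All list inputs (panels, mtDNA calls, CNVs, STR genotypes, curated
    lists, evidence, review flags, phenotype packets) are headered TSVs
    documented in the reader docstrings.  SNV/indel coordinates are
    1-based inclusive; CNV/exon/STR intervals 0-based half-open.
OBO
    The HPO ontology, loaded with obonet.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import networkx as nx
import obonet
import pandas as pd
import pysam

from .types import (
    CnvCall,
    ExonModel,
    FamilyMember,
    MtdnaCall,
    NuclearVariant,
    Panel,
    PhenotypePacket,
    ReviewFlags,
    StrGenotype,
    StrLocusDef,
    ValidationError,
)

log = logging.getLogger(__name__)

#: translation from annotation-tool consequence dialects to the fixed enum
DEFAULT_CONSEQUENCE_MAP = {
    "stop_gained": "nonsense",
    "frameshift_variant": "frameshift",
    "splice_donor_variant": "essential_splice_donor",
    "splice_acceptor_variant": "essential_splice_acceptor",
    "splice_region_variant": "splice_region",
    "missense_variant": "missense",
    "inframe_deletion": "inframe_indel",
    "inframe_insertion": "inframe_indel",
    "synonymous_variant": "synonymous",
    "intron_variant": "intronic",
}


@dataclass
class VcfConfig:
    """Which INFO keys carry the annotations (the dialect is configurable)."""

    gene_key: str = "GENE"
    consequence_key: str = "CSQ"
    af_key: str = "AF"
    consequence_map: dict[str, str] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# pedigree


def read_pedigree(path: str | Path) -> dict[str, list[FamilyMember]]:
    """Read a PED file into members grouped by family.

    Affected status is column 6 (2 = affected).  The proband is the
    member flagged in the optional proband column, else the first
    affected member listed.  Referential and cycle checks are applied
    per family.
    """
    families: dict[str, list[FamilyMember]] = {}
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split()
            if len(cols) < 6:
                raise ValidationError(f"{path.name}:{lineno}: expected >=6 columns, got {len(cols)}")
            fam, sid, father, mother, sex_code, pheno = cols[:6]
            try:
                member = FamilyMember(
                    family_id=fam,
                    sample_id=sid,
                    father_id=None if father == "0" else father,
                    mother_id=None if mother == "0" else mother,
                    sex={"1": "male", "2": "female"}.get(sex_code, "unknown"),
                    affected=pheno == "2",
                    is_proband=len(cols) > 6 and cols[6] == "1",
                    age_at_enrolment=int(cols[7]) if len(cols) > 7 and cols[7] != "." else None,
                )
            except (ValueError, ValidationError) as exc:
                raise ValidationError(f"{path.name}:{lineno}: {exc}") from exc
            families.setdefault(fam, []).append(member)

    from .types import FamilyBundle  # deferred to avoid import noise at module top

    for fam, members in families.items():
        if not any(m.is_proband for m in members):
            affected = [m for m in members if m.affected]
            if not affected:
                raise ValidationError(f"family {fam}: no affected member to take as proband")
            affected[0].is_proband = True
        FamilyBundle(family_id=fam, members=members).validate()
    return families


def write_pedigree(families: dict[str, list[FamilyMember]], path: str | Path) -> None:
    sex_code = {"male": "1", "female": "2", "unknown": "0"}
    with open(path, "w") as fh:
        for fam in sorted(families):
            for m in families[fam]:
                fh.write(
                    "\t".join(
                        [
                            m.family_id,
                            m.sample_id,
                            m.father_id or "0",
                            m.mother_id or "0",
                            sex_code[m.sex],
                            "2" if m.affected else "1",
                            "1" if m.is_proband else "0",
                            "." if m.age_at_enrolment is None else str(m.age_at_enrolment),
                        ]
                    )
                    + "\n"
                )


# ---------------------------------------------------------------------------
# panels


def read_panels(paths: list[str | Path]) -> list[Panel]:
    """Read panel TSVs (columns: panel_id, name, gene, confidence).

    A gene duplicated within a panel is collapsed keeping the highest
    confidence (green > amber > red).
    """
    rank = {"green": 0, "amber": 1, "red": 2}
    panels = []
    for path in paths:
        df = pd.read_csv(path, sep="\t", dtype=str)
        for col in ("panel_id", "name", "gene", "confidence"):
            if col not in df.columns:
                raise ValidationError(f"{path}: missing column {col!r}")
        if df.empty:
            raise ValidationError(f"{path}: empty gene list")
        for (pid, name), grp in df.groupby(["panel_id", "name"], sort=True):
            genes: dict[str, str] = {}
            for _, row in grp.iterrows():
                g, c = row["gene"], row["confidence"]
                if g not in genes or rank[c] < rank[genes[g]]:
                    genes[g] = c
            panels.append(Panel(panel_id=pid, name=name, genes=genes))
    return panels


def write_panel(panel: Panel, path: str | Path) -> None:
    rows = [
        {"panel_id": panel.panel_id, "name": panel.name, "gene": g, "confidence": c}
        for g, c in sorted(panel.genes.items())
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# nuclear family VCF

_GT_STR = {"hom_ref": (0, 0), "het": (0, 1), "hom_alt": (1, 1), "hemi": (1,)}


def write_family_vcf(
    variants: list[NuclearVariant],
    sample_ids: list[str],
    path: str | Path,
    config: VcfConfig | None = None,
) -> None:
    """Write decomposed variants to an uncompressed VCF 4.2 file."""
    config = config or VcfConfig()
    header = pysam.VariantHeader()
    contigs = sorted({v.chrom for v in variants}, key=lambda c: (len(c), c))
    for c in contigs:
        header.contigs.add(c, length=250_000_000)
    header.filters.add("LowQual", None, None, "Low quality call")
    header.info.add(config.gene_key, 1, "String", "Gene symbol")
    header.info.add(config.consequence_key, 1, "String", "Consequence category")
    header.info.add(config.af_key, "A", "Float", "Population allele frequency")
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("DP", 1, "Integer", "Read depth")
    header.formats.add("GQ", 1, "Integer", "Genotype quality")
    for s in sample_ids:
        header.add_sample(s)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for v in sorted(variants, key=lambda v: (v.chrom, v.pos, v.alt)):
            rec = out.new_record(
                contig=v.chrom, start=v.pos - 1, alleles=(v.ref, v.alt), filter="PASS" if v.filter_pass else "LowQual"
            )
            rec.info[config.gene_key] = v.gene
            rec.info[config.consequence_key] = v.consequence
            if v.population_af is not None:
                rec.info[config.af_key] = (v.population_af,)
            for s in sample_ids:
                gt = v.genotypes.get(s, "missing")
                rec.samples[s]["GT"] = _GT_STR.get(gt, (None,))
                if s in v.depth:
                    rec.samples[s]["DP"] = v.depth[s]
                if s in v.gq:
                    rec.samples[s]["GQ"] = v.gq[s]
            out.write(rec)


def _decode_genotype(gt: Optional[tuple], allele_index: int) -> str:
    if gt is None or all(a is None for a in gt):
        return "missing"
    called = [a for a in gt if a is not None]
    hits = sum(1 for a in called if a == allele_index)
    if len(called) == 1:
        return "hemi" if hits == 1 else "hom_ref"
    if hits == 0:
        return "hom_ref"
    if hits == 1:
        return "het"
    return "hom_alt"


def read_family_vcf(
    path: str | Path,
    pedigree: list[FamilyMember],
    config: VcfConfig | None = None,
) -> list[NuclearVariant]:
    """Read a multi-sample family VCF into decomposed variant records.

    One record is returned per ALT allele per site; FILTER != PASS is
    recorded in ``filter_pass``.  A sample in the VCF that is absent
    from the pedigree is an error; a missing configured INFO key leaves
    the field unset with a logged warning.
    """
    config = config or VcfConfig()
    cons_map = {**DEFAULT_CONSEQUENCE_MAP, **config.consequence_map}
    ped_ids = {m.sample_id for m in pedigree}
    out: list[NuclearVariant] = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        unknown = set(samples) - ped_ids
        if unknown:
            raise ValidationError(f"samples in VCF absent from pedigree: {sorted(unknown)}")
        def info_get(rec, key):
            # an INFO key absent from the header raises instead of
            # returning a default; treat both cases as "not annotated"
            try:
                return rec.info.get(key)
            except (KeyError, ValueError):
                return None

        for rec in vcf:
            filter_pass = "PASS" in rec.filter or len(rec.filter) == 0
            gene = info_get(rec, config.gene_key)
            cons_raw = info_get(rec, config.consequence_key)
            af = info_get(rec, config.af_key)
            if gene is None or cons_raw is None:
                log.warning("missing annotation INFO key at %s:%d", rec.chrom, rec.pos)
            if isinstance(af, tuple):
                af_list = list(af)
            else:
                af_list = [af] * len(rec.alts or ())
            for i, alt in enumerate(rec.alts or ()):
                cons = cons_map.get(cons_raw, cons_raw) if cons_raw else "other"
                af_i = af_list[i] if i < len(af_list) else None
                out.append(
                    NuclearVariant(
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref=rec.ref,
                        alt=alt,
                        gene=gene or "",
                        consequence=cons if cons in DEFAULT_CONSEQUENCE_MAP.values() or cons in {
                            "nonsense", "frameshift", "essential_splice_donor",
                            "essential_splice_acceptor", "splice_region", "missense",
                            "inframe_indel", "synonymous", "intronic", "other",
                        } else "other",
                        population_af=float(af_i) if af_i is not None else None,
                        genotypes={
                            s: _decode_genotype(rec.samples[s].get("GT"), i + 1) for s in samples
                        },
                        depth={
                            s: int(rec.samples[s]["DP"])
                            for s in samples
                            if rec.samples[s].get("DP") is not None
                        },
                        gq={
                            s: int(rec.samples[s]["GQ"])
                            for s in samples
                            if rec.samples[s].get("GQ") is not None
                        },
                        filter_pass=filter_pass,
                    )
                )
    return out


# ---------------------------------------------------------------------------
# mtDNA tables


def read_mtdna_calls(path: str | Path) -> dict[str, list[MtdnaCall]]:
    """Read mtDNA calls (sample_id, position, ref, alt, allele_fraction,
    depth, forward_alt_reads, reverse_alt_reads), grouped by sample."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "ref": str, "alt": str})
    calls: dict[str, list[MtdnaCall]] = {}
    for _, r in df.iterrows():
        call = MtdnaCall(
            position=int(r["position"]),
            ref=r["ref"],
            alt=r["alt"],
            allele_fraction=float(r["allele_fraction"]),
            depth=int(r["depth"]),
            forward_alt_reads=int(r["forward_alt_reads"]),
            reverse_alt_reads=int(r["reverse_alt_reads"]),
            sample_id=r["sample_id"],
        )
        calls.setdefault(call.sample_id, []).append(call)
    return calls


def write_mtdna_calls(calls: dict[str, list[MtdnaCall]], path: str | Path) -> None:
    rows = [
        {
            "sample_id": c.sample_id,
            "position": c.position,
            "ref": c.ref,
            "alt": c.alt,
            "allele_fraction": c.allele_fraction,
            "depth": c.depth,
            "forward_alt_reads": c.forward_alt_reads,
            "reverse_alt_reads": c.reverse_alt_reads,
        }
        for sid in sorted(calls)
        for c in calls[sid]
    ]
    pd.DataFrame(
        rows,
        columns=[
            "sample_id", "position", "ref", "alt", "allele_fraction",
            "depth", "forward_alt_reads", "reverse_alt_reads",
        ],
    ).to_csv(path, sep="\t", index=False)


def read_pathogenic_mtdna(path: str | Path) -> list[tuple[int, str, str, str, str]]:
    """Read the curated pathogenic mtDNA list (position, ref, alt, label, gene)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"ref": str, "alt": str})
    return [
        (int(r["position"]), r["ref"], r["alt"], r["label"], r["gene"]) for _, r in df.iterrows()
    ]


# ---------------------------------------------------------------------------
# CNV / exon / STR tables


def read_cnv_calls(path: str | Path) -> list[CnvCall]:
    """Read CNV calls (sample_id, chrom, start, end, type, filter,
    copy_number); intervals 0-based half-open."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "chrom": str})
    return [
        CnvCall(
            chrom=r["chrom"],
            start=int(r["start"]),
            end=int(r["end"]),
            type=r["type"],
            filter_pass=r["filter"] == "PASS",
            sample_id=r["sample_id"],
            copy_number=None if pd.isna(r.get("copy_number")) else int(r["copy_number"]),
        )
        for _, r in df.iterrows()
    ]


def write_cnv_calls(calls: list[CnvCall], path: str | Path) -> None:
    rows = [
        {
            "sample_id": c.sample_id,
            "chrom": c.chrom,
            "start": c.start,
            "end": c.end,
            "type": c.type,
            "filter": "PASS" if c.filter_pass else "LowQual",
            "copy_number": c.copy_number,
        }
        for c in calls
    ]
    pd.DataFrame(
        rows, columns=["sample_id", "chrom", "start", "end", "type", "filter", "copy_number"]
    ).to_csv(path, sep="\t", index=False)


def read_exon_models(path: str | Path) -> list[ExonModel]:
    """Read exon models (gene, chrom, start, end; 0-based half-open)."""
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "chrom": str})
    models: dict[str, list[tuple[str, int, int]]] = {}
    for _, r in df.iterrows():
        models.setdefault(r["gene"], []).append((r["chrom"], int(r["start"]), int(r["end"])))
    return [ExonModel(gene=g, exons=sorted(exons)) for g, exons in sorted(models.items())]


def write_exon_models(models: list[ExonModel], path: str | Path) -> None:
    rows = [
        {"gene": m.gene, "chrom": c, "start": s, "end": e}
        for m in models
        for c, s, e in m.exons
    ]
    pd.DataFrame(rows, columns=["gene", "chrom", "start", "end"]).to_csv(path, sep="\t", index=False)


def read_str_genotypes(path: str | Path) -> list[StrGenotype]:
    """Read STR genotypes (sample_id, locus, allele1_repeats,
    allele2_repeats, visual_review)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "locus": str})
    return [
        StrGenotype(
            sample_id=r["sample_id"],
            locus=r["locus"],
            allele1_repeats=int(r["allele1_repeats"]),
            allele2_repeats=None if pd.isna(r["allele2_repeats"]) else int(r["allele2_repeats"]),
            visual_review=r["visual_review"],
        )
        for _, r in df.iterrows()
    ]


def write_str_genotypes(genotypes: list[StrGenotype], path: str | Path) -> None:
    rows = [
        {
            "sample_id": g.sample_id,
            "locus": g.locus,
            "allele1_repeats": g.allele1_repeats,
            "allele2_repeats": g.allele2_repeats,
            "visual_review": g.visual_review,
        }
        for g in genotypes
    ]
    pd.DataFrame(
        rows, columns=["sample_id", "locus", "allele1_repeats", "allele2_repeats", "visual_review"]
    ).to_csv(path, sep="\t", index=False)


def read_str_loci(path: str | Path) -> dict[str, StrLocusDef]:
    """Read the STR locus config (locus, repeat_unit, normal_max,
    premut_lo, premut_hi, full_min, inheritance_mode)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"locus": str, "repeat_unit": str})
    loci = {}
    for _, r in df.iterrows():
        premut = None
        if not pd.isna(r["premut_lo"]) and not pd.isna(r["premut_hi"]):
            premut = (int(r["premut_lo"]), int(r["premut_hi"]))
        loci[r["locus"]] = StrLocusDef(
            locus=r["locus"],
            repeat_unit=r["repeat_unit"],
            normal_max=int(r["normal_max"]),
            premutation_range=premut,
            full_min=int(r["full_min"]),
            inheritance_mode=r["inheritance_mode"],
        )
    return loci


# ---------------------------------------------------------------------------
# curated nuclear lists / evidence / review / phenotypes


def read_clinvar_plp(path: str | Path) -> tuple[set[tuple[str, int, str, str]], str]:
    """Read the ClinVar-style P/LP table (chrom, pos, ref, alt, class).

    The genome-build label is carried in a ``#build=`` comment on the
    first line; it defaults to GRCh38.
    """
    build = "GRCh38"
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#build="):
            build = first.strip().split("=", 1)[1]
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str, "ref": str, "alt": str})
    table = set()
    for _, r in df.iterrows():
        if r["class"] not in {"P", "LP", "P/LP"}:
            raise ValidationError(f"unknown ClinVar class {r['class']!r}")
        table.add((r["chrom"], int(r["pos"]), r["ref"], r["alt"]))
    return table, build


def read_mito_genes(path: str | Path) -> set[str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return set(df["gene"])


def read_evidence(path: str | Path) -> dict[str, list[tuple[str, Optional[str]]]]:
    """Read ACMG evidence (variant_key, code, modifier; '.' = intrinsic)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    ev: dict[str, list[tuple[str, Optional[str]]]] = {}
    for _, r in df.iterrows():
        modifier = None if pd.isna(r["modifier"]) or r["modifier"] == "." else r["modifier"]
        ev.setdefault(r["variant_key"], []).append((r["code"], modifier))
    return ev


def write_evidence(ev: dict[str, list[tuple[str, Optional[str]]]], path: str | Path) -> None:
    rows = [
        {"variant_key": k, "code": code, "modifier": modifier or "."}
        for k in sorted(ev)
        for code, modifier in ev[k]
    ]
    pd.DataFrame(rows, columns=["variant_key", "code", "modifier"]).to_csv(
        path, sep="\t", index=False
    )


def read_review_flags(path: str | Path) -> dict[str, dict[str, ReviewFlags]]:
    """Read clinical-review flags (family_id, gene, fit, contribution,
    adjustment), keyed family -> gene."""
    df = pd.read_csv(path, sep="\t", dtype={"family_id": str, "gene": str})
    out: dict[str, dict[str, ReviewFlags]] = {}
    for _, r in df.iterrows():
        out.setdefault(r["family_id"], {})[r["gene"]] = ReviewFlags(
            fit=r["fit"], contribution=r["contribution"], adjustment=int(r["adjustment"])
        )
    return out


def write_review_flags(flags: dict[str, dict[str, ReviewFlags]], path: str | Path) -> None:
    rows = [
        {
            "family_id": fid,
            "gene": gene,
            "fit": f.fit,
            "contribution": f.contribution,
            "adjustment": f.adjustment,
        }
        for fid in sorted(flags)
        for gene, f in sorted(flags[fid].items())
    ]
    pd.DataFrame(
        rows, columns=["family_id", "gene", "fit", "contribution", "adjustment"]
    ).to_csv(path, sep="\t", index=False)


def read_phenotype_packets(path: str | Path) -> dict[str, PhenotypePacket]:
    """Read phenotype packets (sample_id, hpo_term), one row per term."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    packets: dict[str, PhenotypePacket] = {}
    for _, r in df.iterrows():
        sid = r["sample_id"]
        if sid not in packets:
            packets[sid] = PhenotypePacket(sample_id=sid, hpo_terms=set())
        packets[sid].hpo_terms.add(r["hpo_term"])
    return packets


def write_phenotype_packets(packets: dict[str, PhenotypePacket], path: str | Path) -> None:
    rows = [
        {"sample_id": sid, "hpo_term": t}
        for sid in sorted(packets)
        for t in sorted(packets[sid].hpo_terms)
    ]
    pd.DataFrame(rows, columns=["sample_id", "hpo_term"]).to_csv(path, sep="\t", index=False)


def read_external_ranks(path: str | Path) -> dict[str, list[tuple[str, int]]]:
    """Read prioritiser ranks (sample_id, variant_key, rank) per proband."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "variant_key": str})
    out: dict[str, list[tuple[str, int]]] = {}
    for _, r in df.iterrows():
        out.setdefault(r["sample_id"], []).append((r["variant_key"], int(r["rank"])))
    return out


def write_external_ranks(ranks: dict[str, list[tuple[str, int]]], path: str | Path) -> None:
    rows = [
        {"sample_id": sid, "variant_key": k, "rank": rank}
        for sid in sorted(ranks)
        for k, rank in ranks[sid]
    ]
    pd.DataFrame(rows, columns=["sample_id", "variant_key", "rank"]).to_csv(
        path, sep="\t", index=False
    )


def read_ontology(path: str | Path) -> nx.MultiDiGraph:
    """Load an OBO ontology (HPO or compatible) as an obonet graph."""
    return obonet.read_obo(str(path))


def read_mdc_items(path: str | Path) -> dict[str, tuple[str, int]]:
    """Read the score item map (hpo_term, section, points)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"hpo_term": str, "section": str})
    return {r["hpo_term"]: (r["section"], int(r["points"])) for _, r in df.iterrows()}


def default_data_path(name: str) -> Path:
    """Path to a data table shipped with the package."""
    return Path(__file__).parent / "data" / name
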