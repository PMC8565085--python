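"""End-to-end pipeline: load a cohort directory, analyse, write reports.

Stage order follows the analysis workflow: nuclear tiering and the
candidate channels, then mtDNA, CNV and STR triage, ACMG evidence
combining, per-family aggregation and the cohort summary.  All output
tables are sorted by (family, gene, variant key) so re-running on
identical inputs yields byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
import pandas as pd

from . import io as mio
from .aggregate import analyse_bundle, summarise_cohort
from .mtdna import MtdnaQcConfig
from .tiering import DeNovoQc, RarityConfig
from .types import CandidateDiagnosis, CohortSummary, CuratedLists, FamilyBundle

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths and thresholds for one pipeline run.

    Optional inputs (ranks, review, phenotypes, ontology) may be absent
    from the cohort directory; thresholds default to the documented
    values and are echoed into the summary for provenance.
    """

    cohort_dir: Path
    out_dir: Path
    rarity: RarityConfig = field(default_factory=RarityConfig)
    de_novo_qc: DeNovoQc = field(default_factory=DeNovoQc)
    mtdna_qc: MtdnaQcConfig = field(default_factory=MtdnaQcConfig)
    build: str = "GRCh38"
    seed: int = 0


def load_cohort_dir(cohort_dir: str | Path):
    """Reconstruct family bundles and reference inputs from a cohort directory."""
    d = Path(cohort_dir)
    families = mio.read_pedigree(d / "pedigree.ped")
    panels = {p.panel_id: p for p in mio.read_panels(sorted((d / "panels").glob("*.tsv")))}
    applied = pd.read_csv(d / "applied_panels.tsv", sep="\t", dtype=str)
    mt_calls = mio.read_mtdna_calls(d / "mtdna_calls.tsv") if (d / "mtdna_calls.tsv").exists() else {}
    cnvs = mio.read_cnv_calls(d / "cnv_calls.tsv") if (d / "cnv_calls.tsv").exists() else []
    strs = mio.read_str_genotypes(d / "str_genotypes.tsv") if (d / "str_genotypes.tsv").exists() else []
    evidence = mio.read_evidence(d / "evidence.tsv") if (d / "evidence.tsv").exists() else {}
    review = mio.read_review_flags(d / "review.tsv") if (d / "review.tsv").exists() else {}
    ranks = mio.read_external_ranks(d / "ranks.tsv") if (d / "ranks.tsv").exists() else {}
    packets = (
        mio.read_phenotype_packets(d / "phenotypes.tsv") if (d / "phenotypes.tsv").exists() else {}
    )
    clinvar, build = (
        mio.read_clinvar_plp(d / "clinvar_plp.tsv") if (d / "clinvar_plp.tsv").exists() else (set(), "GRCh38")
    )
    mt_path = d / "pathogenic_mtdna.tsv"
    curated = CuratedLists(
        pathogenic_mtdna=mio.read_pathogenic_mtdna(
            mt_path if mt_path.exists() else mio.default_data_path("pathogenic_mtdna.tsv")
        ),
        clinvar_plp=clinvar,
        clinvar_build=build,
        mito_genes=mio.read_mito_genes(d / "mito_genes.tsv") if (d / "mito_genes.tsv").exists() else set(),
        str_loci=mio.read_str_loci(
            d / "str_loci.tsv" if (d / "str_loci.tsv").exists() else mio.default_data_path("str_loci.tsv")
        ),
    )
    exons = mio.read_exon_models(d / "exons.tsv") if (d / "exons.tsv").exists() else []

    sample_to_fid = {m.sample_id: fid for fid, ms in families.items() for m in ms}
    bundles: dict[str, FamilyBundle] = {}
    for fid, members in sorted(families.items()):
        b = FamilyBundle(family_id=fid, members=members)
        vcf = d / "families" / f"{fid}.vcf"
        if vcf.exists():
            b.nuclear_variants = mio.read_family_vcf(vcf, members, mio.VcfConfig())
        b.applied_panel_ids = sorted(applied.loc[applied["family_id"] == fid, "panel_id"])
        member_ids = {m.sample_id for m in members}
        b.mtdna_calls = {sid: calls for sid, calls in mt_calls.items() if sid in member_ids}
        b.cnv_calls = [c for c in cnvs if c.sample_id in member_ids]
        b.str_genotypes = [g for g in strs if g.sample_id in member_ids]
        b.review = review.get(fid, {})
        b.external_ranks = ranks.get(f"{fid}_P", [])
        b.phenotypes = {sid: p for sid, p in packets.items() if sid in member_ids}
        bundles[fid] = b
    # evidence keys are variant-level and unambiguous; attach the full map
    for b in bundles.values():
        b.evidence = evidence
    return bundles, panels, curated, exons


def analyse_cohort(
    bundles: dict[str, FamilyBundle],
    panels,
    curated: CuratedLists,
    exon_models=None,
    rarity: RarityConfig | None = None,
    de_novo_qc: DeNovoQc | None = None,
    mtdna_qc: MtdnaQcConfig | None = None,
    build: str = "GRCh38",
) -> tuple[dict[str, list[CandidateDiagnosis]], CohortSummary]:
    """Analyse every family and summarise the cohort."""
    results = {}
    for fid in sorted(bundles):
        results[fid] = analyse_bundle(
            bundles[fid], panels, curated, exon_models, rarity, de_novo_qc, mtdna_qc, build
        )
    summary = summarise_cohort(results, {fid: b.members for fid, b in bundles.items()})
    return results, summary


def diagnoses_frame(results: dict[str, list[CandidateDiagnosis]]) -> pd.DataFrame:
    rows = []
    for fid in sorted(results):
        for d in results[fid]:
            rows.append(
                {
                    "family_id": d.family_id,
                    "genes": ";".join(d.genes),
                    "variants": ";".join(d.variants),
                    "acmg": ";".join(d.acmg_classes),
                    "inheritance": d.inheritance,
                    "de_novo": d.de_novo,
                    "confidence": d.confidence,
                    "contribution": d.contribution,
                    "route": d.route,
                    "mitochondrial": d.is_mitochondrial,
                }
            )
    df = pd.DataFrame(
        rows,
        columns=[
            "family_id", "genes", "variants", "acmg", "inheritance", "de_novo",
            "confidence", "contribution", "route", "mitochondrial",
        ],
    )
    return df.sort_values(["family_id", "genes", "variants"]).reset_index(drop=True)


def summary_dict(summary: CohortSummary, config: RunConfig | None = None) -> dict:
    out = {
        "n_families": summary.n_families,
        "n_diagnosed": summary.n_diagnosed,
        "n_definite": summary.n_definite,
        "n_probable": summary.n_probable,
        "n_possible": summary.n_possible,
        "n_partial": summary.n_partial,
        "n_mitochondrial": summary.n_mito,
        "n_non_mitochondrial": summary.n_non_mito,
        "route_counts": summary.route_counts,
        "distinct_genes": summary.distinct_genes,
        "n_dual_diagnosis_families": summary.n_dual,
        "yield_by_stratum": {k: list(v) for k, v in sorted(summary.yield_by_stratum.items())},
        "inheritance_breakdown": summary.inheritance_breakdown,
    }
    if config is not None:
        out["thresholds"] = {
            "rarity_af_monoallelic": config.rarity.af_monoallelic,
            "rarity_af_biallelic": config.rarity.af_biallelic,
            "de_novo_min_depth": config.de_novo_qc.min_depth,
            "de_novo_min_gq": config.de_novo_qc.min_gq,
            "mtdna_min_heteroplasmy": config.mtdna_qc.min_heteroplasmy,
            "mtdna_min_depth": config.mtdna_qc.min_depth,
            "homoplasmy_cutoff": config.mtdna_qc.homoplasmy_cutoff,
            "seed": config.seed,
        }
    return out


def run_pipeline(config: RunConfig) -> CohortSummary:
    """Execute the full pipeline for a cohort directory.

    Writes ``diagnoses.tsv`` and ``summary.json`` under the output
    directory and returns the cohort summary.  Any stage error aborts
    with a stage-named message and removes partial outputs.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    diag_path, summary_path = out / "diagnoses.tsv", out / "summary.json"
    try:
        try:
            bundles, panels, curated, exons = load_cohort_dir(config.cohort_dir)
        except Exception as exc:
            raise RuntimeError(f"load stage failed: {exc}") from exc
        try:
            results, summary = analyse_cohort(
                bundles, panels, curated, exons,
                config.rarity, config.de_novo_qc, config.mtdna_qc, config.build,
            )
        except Exception as exc:
            raise RuntimeError(f"analysis stage failed: {exc}") from exc
        diagnoses_frame(results).to_csv(diag_path, sep="\t", index=False)
        with open(summary_path, "w") as fh:
            json.dump(summary_dict(summary, config), fh, indent=2, sort_keys=True)
            fh.write("\n")
    except Exception:
        for p in (diag_path, summary_path):
            if p.exists():
                p.unlink()
        raise
    return summary
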