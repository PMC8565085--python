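"""Shared fixtures: the published-tables cohort, its analysis, and helpers."""

from __future__ import annotations

import pytest

from mitodx.pipeline import analyse_cohort
from mitodx.synthetic import build_ontology, build_tables_fixture, default_mdc_config
from mitodx.types import FamilyBundle, FamilyMember, NuclearVariant


@pytest.fixture(scope="session")
def fixture_cohort():
    return build_tables_fixture()


@pytest.fixture(scope="session")
def fixture_analysis(fixture_cohort):
    c = fixture_cohort
    results, summary = analyse_cohort(c.bundles, c.panels, c.curated, c.exon_models)
    return results, summary


@pytest.fixture(scope="session")
def ontology():
    return build_ontology()


@pytest.fixture(scope="session")
def mdc_config():
    return default_mdc_config()


def make_trio(fid: str = "T1") -> FamilyBundle:
    """A minimal trio: affected child proband, unaffected parents."""
    members = [
        FamilyMember(fid, f"{fid}_P", f"{fid}_FA", f"{fid}_MO", "female", True, 5, True),
        FamilyMember(fid, f"{fid}_FA", None, None, "male", False, 40),
        FamilyMember(fid, f"{fid}_MO", None, None, "female", False, 38),
    ]
    return FamilyBundle(family_id=fid, members=members)


def make_singleton(fid: str = "S1", sex: str = "male") -> FamilyBundle:
    members = [FamilyMember(fid, f"{fid}_P", None, None, sex, True, 30, True)]
    return FamilyBundle(family_id=fid, members=members)


def trio_variant(
    bundle: FamilyBundle,
    gt_child: str,
    gt_father: str = "hom_ref",
    gt_mother: str = "hom_ref",
    consequence: str = "missense",
    gene: str = "GENE1",
    af: float = 0.0,
    depth: int = 30,
    gq: int = 99,
    chrom: str = "1",
    pos: int = 1000,
    filter_pass: bool = True,
) -> NuclearVariant:
    fid = bundle.family_id
    gts = {f"{fid}_P": gt_child}
    if bundle.member(f"{fid}_FA") is not None:
        gts[f"{fid}_FA"] = gt_father
    if bundle.member(f"{fid}_MO") is not None:
        gts[f"{fid}_MO"] = gt_mother
    return NuclearVariant(
        chrom=chrom,
        pos=pos,
        ref="A",
        alt="G",
        gene=gene,
        consequence=consequence,
        population_af=af,
        genotypes=gts,
        depth={s: depth for s in gts},
        gq={s: gq for s in gts},
        filter_pass=filter_pass,
    )
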