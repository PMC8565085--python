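"""Shared data model for the diagnostic pipeline.

Coordinate conventions
----------------------
Nuclear SNV/indel records use the VCF convention: 1-based, inclusive.
Interval records (CNV calls, exon models, STR locus coordinates) are
0-based half-open.  mtDNA positions are 1-based on the 16,569 bp rCRS
circle and reported in transcript-free ``m.POS`` notation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

MT_LENGTH = 16_569

SEXES = {"male", "female", "unknown"}
GENOTYPES = {"hom_ref", "het", "hom_alt", "hemi", "missing"}
CONSEQUENCES = {
    "nonsense",
    "frameshift",
    "essential_splice_donor",
    "essential_splice_acceptor",
    "splice_region",
    "missense",
    "inframe_indel",
    "synonymous",
    "intronic",
    "other",
}
#: consequences counted as unambiguous loss of function for tier 1
LOF_CONSEQUENCES = {
    "nonsense",
    "frameshift",
    "essential_splice_donor",
    "essential_splice_acceptor",
}

CONFIDENCES = ("possible", "probable", "definite")
ROUTES = ("tier12", "other_snv", "cnv", "str", "mtdna")
INHERITANCES = {
    "monoallelic_de_novo",
    "monoallelic_AD",
    "monoallelic_unknown",
    "biallelic",
    "x_linked_recessive",
    "x_linked_dominant",
    "mtdna_maternal",
    "mtdna_de_novo",
    "mtdna_unknown",
}


class ValidationError(ValueError):
    """Raised when an input record violates the data-model invariants."""


@dataclass
class FamilyMember:
    family_id: str
    sample_id: str
    father_id: Optional[str] = None
    mother_id: Optional[str] = None
    sex: str = "unknown"
    affected: bool = False
    age_at_enrolment: Optional[int] = None
    is_proband: bool = False

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValidationError(f"unknown sex {self.sex!r} for {self.sample_id}")
        if self.age_at_enrolment is not None and self.age_at_enrolment < 0:
            raise ValidationError(f"negative age for {self.sample_id}")


@dataclass
class NuclearVariant:
    """A decomposed (one ALT per record) nuclear SNV or small indel."""

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    consequence: str
    population_af: Optional[float]
    genotypes: dict[str, str]
    depth: dict[str, int] = field(default_factory=dict)
    gq: dict[str, int] = field(default_factory=dict)
    filter_pass: bool = True

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValidationError(f"ref == alt at {self.chrom}:{self.pos}")
        if self.consequence not in CONSEQUENCES:
            raise ValidationError(f"unknown consequence {self.consequence!r}")
        for s, g in self.genotypes.items():
            if g not in GENOTYPES:
                raise ValidationError(f"unknown genotype {g!r} for sample {s}")
        if self.population_af is not None and not 0.0 <= self.population_af <= 1.0:
            raise ValidationError(f"population_af out of [0,1]: {self.population_af}")

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"

    def carried_by(self, sample_id: str) -> bool:
        return self.genotypes.get(sample_id, "missing") in {"het", "hom_alt", "hemi"}


@dataclass
class Panel:
    """A virtual gene panel; ``genes`` maps symbol -> confidence rating."""

    panel_id: str
    name: str
    genes: dict[str, str]  # symbol -> {green, amber, red}

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValidationError(f"panel {self.panel_id} has an empty gene list")
        bad = {c for c in self.genes.values()} - {"green", "amber", "red"}
        if bad:
            raise ValidationError(f"panel {self.panel_id}: unknown confidences {bad}")


@dataclass
class PhenotypePacket:
    sample_id: str
    hpo_terms: set[str]
    free_flags: dict[str, bool] = field(default_factory=dict)


@dataclass
class MtdnaCall:
    """One mtDNA substitution/indel call with heteroplasmy and QC fields.

    ``allele_fraction`` is the heteroplasmy level in percent (0-100).
    """

    position: int
    ref: str
    alt: str
    allele_fraction: float
    depth: int
    forward_alt_reads: int
    reverse_alt_reads: int
    sample_id: str

    def __post_init__(self) -> None:
        if not 1 <= self.position <= MT_LENGTH:
            raise ValidationError(f"mtDNA position out of range: {self.position}")
        if not 0.0 <= self.allele_fraction <= 100.0:
            raise ValidationError(f"allele_fraction out of [0,100]: {self.allele_fraction}")
        if self.forward_alt_reads + self.reverse_alt_reads > self.depth:
            raise ValidationError(
                f"alt reads exceed depth at m.{self.position}{self.ref}>{self.alt}"
            )

    @property
    def key(self) -> str:
        return f"mt:{self.position}:{self.ref}:{self.alt}"

    @property
    def hgvs(self) -> str:
        return f"m.{self.position}{self.ref}>{self.alt}"


@dataclass
class MtdnaFinding:
    call: MtdnaCall
    pathogenic_label: str
    gene: str
    homoplasmic: bool
    inheritance: str = "unknown"  # maternal / de_novo / unknown
    mother_subthreshold: bool = False  # 0% < mother AF < detection threshold


@dataclass
class CnvCall:
    """A copy-number call; interval is 0-based half-open."""

    chrom: str
    start: int
    end: int
    type: str  # loss / gain / loh
    filter_pass: bool
    sample_id: str
    copy_number: Optional[int] = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(f"CNV start >= end on {self.chrom}")
        if self.type not in {"loss", "gain", "loh"}:
            raise ValidationError(f"unknown CNV type {self.type!r}")

    @property
    def key(self) -> str:
        return f"cnv:{self.chrom}:{self.start}:{self.end}:{self.type}"


@dataclass
class ExonModel:
    gene: str
    exons: list[tuple[str, int, int]]  # (chrom, start, end), 0-based half-open


@dataclass
class StrLocusDef:
    locus: str
    repeat_unit: str
    normal_max: int
    premutation_range: Optional[tuple[int, int]]
    full_min: int
    inheritance_mode: str  # dominant / x_linked / recessive

    def __post_init__(self) -> None:
        if self.normal_max >= self.full_min:
            raise ValidationError(f"{self.locus}: normal_max >= full_min")
        if self.premutation_range is not None:
            lo, hi = self.premutation_range
            if not (self.normal_max < lo <= hi < self.full_min):
                raise ValidationError(f"{self.locus}: premutation range not between bands")


@dataclass
class StrGenotype:
    sample_id: str
    locus: str
    allele1_repeats: int
    allele2_repeats: Optional[int] = None
    visual_review: str = "not_needed"  # confirmed / rejected / not_needed

    @property
    def key(self) -> str:
        return f"str:{self.locus}:{self.sample_id}"


@dataclass
class StrResult:
    genotype: StrGenotype
    classification: str  # normal / premutation / full_mutation
    causative: bool


@dataclass
class CuratedLists:
    """Curated reference tables used by the matching channels."""

    pathogenic_mtdna: list[tuple[int, str, str, str, str]]  # pos, ref, alt, label, gene
    clinvar_plp: set[tuple[str, int, str, str]]
    clinvar_build: str = "GRCh38"
    mito_genes: set[str] = field(default_factory=set)
    str_loci: dict[str, StrLocusDef] = field(default_factory=dict)


@dataclass
class TierAssignment:
    variant: NuclearVariant
    tier: int
    rule_fired: str
    panels_hit: set[str] = field(default_factory=set)
    de_novo: bool = False
    segregation_consistent: bool = True

    def __post_init__(self) -> None:
        if self.tier not in {1, 2, 3, 4}:
            raise ValidationError(f"tier out of range: {self.tier}")
        if self.tier <= 2 and not self.panels_hit:
            raise ValidationError("tier 1/2 requires a panel hit")
        if not self.rule_fired:
            raise ValidationError("rule_fired must be non-empty")


@dataclass
class CandidateChannelHit:
    variant: NuclearVariant
    channel: str  # tier12 / clinvar_plp / external_rank_top10 / gmc_feedback
    rank: Optional[int] = None

    def __post_init__(self) -> None:
        if self.channel == "external_rank_top10" and not (
            self.rank is not None and 1 <= self.rank <= 10
        ):
            raise ValidationError("external_rank_top10 hit requires rank in [1,10]")


@dataclass
class ReviewFlags:
    """Per-(family, gene) outcome of the manual clinical review.

    ``fit`` records the clinical fit between the participant's phenotype
    and the gene's reported disease (full/partial/none); ``contribution``
    whether the finding explains the whole phenotype or part of it; and
    ``adjustment`` signed confidence steps applied by the reviewer on top
    of the evidence-derived confidence (clinical judgement the rules
    cannot express).
    """

    fit: str = "full"
    contribution: str = "full"
    adjustment: int = 0


@dataclass
class CandidateDiagnosis:
    family_id: str
    genes: list[str]
    variants: list[str]  # variant keys
    acmg_classes: list[str]
    inheritance: str
    confidence: str
    contribution: str
    route: str
    is_mitochondrial: bool
    de_novo: bool = False

    def __post_init__(self) -> None:
        if self.inheritance not in INHERITANCES:
            raise ValidationError(f"unknown inheritance {self.inheritance!r}")
        if self.confidence not in CONFIDENCES:
            raise ValidationError(f"unknown confidence {self.confidence!r}")
        if self.route not in ROUTES:
            raise ValidationError(f"unknown route {self.route!r}")


@dataclass
class FamilyBundle:
    """Everything the pipeline knows about one family."""

    family_id: str
    members: list[FamilyMember]
    nuclear_variants: list[NuclearVariant] = field(default_factory=list)
    mtdna_calls: dict[str, list[MtdnaCall]] = field(default_factory=dict)
    cnv_calls: list[CnvCall] = field(default_factory=list)
    str_genotypes: list[StrGenotype] = field(default_factory=list)
    phenotypes: dict[str, PhenotypePacket] = field(default_factory=dict)
    applied_panel_ids: list[str] = field(default_factory=list)
    evidence: dict[str, list[tuple[str, Optional[str]]]] = field(default_factory=dict)
    review: dict[str, ReviewFlags] = field(default_factory=dict)
    external_ranks: list[tuple[str, int]] = field(default_factory=list)
    gmc_variant_keys: set[str] = field(default_factory=set)

    @property
    def proband(self) -> FamilyMember:
        for m in self.members:
            if m.is_proband:
                return m
        raise ValidationError(f"family {self.family_id} has no proband")

    def member(self, sample_id: Optional[str]) -> Optional[FamilyMember]:
        if sample_id is None:
            return None
        for m in self.members:
            if m.sample_id == sample_id:
                return m
        return None

    def validate(self) -> None:
        probands = [m for m in self.members if m.is_proband]
        if len(probands) != 1:
            raise ValidationError(
                f"family {self.family_id} has {len(probands)} probands, expected 1"
            )
        ids = {m.sample_id for m in self.members}
        for m in self.members:
            for pid in (m.father_id, m.mother_id):
                if pid is not None and pid not in ids:
                    raise ValidationError(
                        f"family {self.family_id}: parent {pid} of {m.sample_id} "
                        "is not a member of the family"
                    )
        # no member may be its own ancestor
        parents = {m.sample_id: {p for p in (m.father_id, m.mother_id) if p} for m in self.members}
        for start in ids:
            seen, stack = set(), [start]
            while stack:
                cur = stack.pop()
                for p in parents.get(cur, ()):
                    if p == start:
                        raise ValidationError(
                            f"family {self.family_id}: cyclic parentage through {start}"
                        )
                    if p not in seen:
                        seen.add(p)
                        stack.append(p)


@dataclass
class MdcConfig:
    """Item map and caps for the HPO-modified mitochondrial disease score."""

    item_map: dict[str, tuple[str, int]]  # term -> (section, points)
    section_caps: dict[str, int]
    clinical_group_cap: int = 4
    total_cap: int = 12


CLINICAL_SECTIONS = ("clinical_muscular", "clinical_cns", "clinical_multisystem")
MDC_SECTIONS = CLINICAL_SECTIONS + ("metabolic_imaging", "morphology")


@dataclass
class MdcScore:
    section_scores: dict[str, int]
    total: int
    band: str  # unlikely / possible / probable / definite


@dataclass
class CohortSummary:
    n_families: int
    n_diagnosed: int
    n_definite: int
    n_probable: int
    n_possible: int
    n_partial: int
    n_mito: int
    n_non_mito: int
    route_counts: dict[str, int]
    distinct_genes: int
    n_dual: int
    yield_by_stratum: dict[str, tuple[int, int]]
    inheritance_breakdown: dict[str, dict[str, int]]
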