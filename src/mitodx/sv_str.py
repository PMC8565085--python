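"""CNV triage by panel-exon overlap and STR expansion classification.

CNV calls are kept only when PASS and interrupting at least one exon of
a gene on an applied panel (no minimum size — single-exon events count).
STR genotypes at the 13 neurological loci are classified against
per-locus normal / premutation / full-mutation thresholds, with the
recessive locus (FXN) requiring expansion of both alleles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .types import CnvCall, ExonModel, Panel, StrGenotype, StrLocusDef, StrResult

log = logging.getLogger(__name__)


@dataclass
class AnnotatedCnv:
    call: CnvCall
    gene_exons: dict[str, list[int]] = field(default_factory=dict)  # gene -> exon indices hit

    @property
    def genes(self) -> list[str]:
        return sorted(self.gene_exons)


def merge_exons(exons: Iterable[tuple[str, int, int]]) -> list[tuple[str, int, int]]:
    """Merge overlapping/adjacent exon intervals per chromosome."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end in exons:
        by_chrom.setdefault(chrom, []).append((start, end))
    merged = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom])
        cur_s, cur_e = ivs[0]
        for s, e in ivs[1:]:
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                merged.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        merged.append((chrom, cur_s, cur_e))
    return merged


def filter_cnvs(
    calls: Iterable[CnvCall],
    exon_models: Iterable[ExonModel],
    applied_panels: Iterable[Panel],
) -> list[AnnotatedCnv]:
    """Retain PASS CNVs that overlap >=1 bp of >=1 panel-gene exon.

    The annotation records, per retained call, every panel gene hit and
    the indices of its exons interrupted.  Intronic-only or non-PASS
    calls are dropped (logged).
    """
    panel_genes = set()
    for p in applied_panels:
        panel_genes.update(p.genes)
    models = [m for m in exon_models if m.gene in panel_genes]
    out = []
    for call in calls:
        if not call.filter_pass:
            log.debug("CNV %s dropped: non-PASS", call.key)
            continue
        ann = AnnotatedCnv(call)
        for model in models:
            hit = [
                i
                for i, (chrom, s, e) in enumerate(model.exons)
                if chrom == call.chrom and s < call.end and call.start < e
            ]
            if hit:
                ann.gene_exons[model.gene] = hit
        if ann.gene_exons:
            out.append(ann)
        else:
            log.debug("CNV %s dropped: no panel-gene exon overlap", call.key)
    return out


def classify_str(
    genotype: StrGenotype,
    locus_def: StrLocusDef,
    proband_age: Optional[int] = None,
) -> StrResult:
    """Classify an STR genotype and flag whether it is potentially causative.

    The class follows the larger allele: ``full_mutation`` at or above
    ``full_min``, ``premutation`` above ``normal_max`` (including any
    explicit premutation band), otherwise ``normal``.  Causative
    requires a full mutation — and at the recessive locus expansion of
    both alleles beyond ``normal_max`` — and survives only when visual
    read review did not reject the call.  ``proband_age`` is carried
    for reporting (age-dependent penetrance is a review concern, not a
    thresholding one).
    """
    if genotype.locus != locus_def.locus:
        raise ValueError(f"genotype locus {genotype.locus} != definition {locus_def.locus}")
    alleles = [genotype.allele1_repeats]
    if genotype.allele2_repeats is not None:
        alleles.append(genotype.allele2_repeats)
    larger = max(alleles)
    if larger >= locus_def.full_min:
        classification = "full_mutation"
    elif larger > locus_def.normal_max:
        classification = "premutation"
    else:
        classification = "normal"
    causative = classification == "full_mutation"
    if locus_def.inheritance_mode == "recessive":
        causative = causative and all(a > locus_def.normal_max for a in alleles)
    if genotype.visual_review == "rejected":
        causative = False
    return StrResult(genotype=genotype, classification=classification, causative=causative)


def classify_str_table(
    genotypes: Iterable[StrGenotype],
    loci: dict[str, StrLocusDef],
    proband_age: Optional[int] = None,
) -> list[StrResult]:
    out = []
    for g in genotypes:
        if g.locus not in loci:
            raise KeyError(f"unknown STR locus {g.locus!r}")
        out.append(classify_str(g, loci[g.locus], proband_age))
    return out
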