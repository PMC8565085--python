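"""mtDNA heteroplasmy filtering, pathogenic-list matching and inheritance.

Calls are retained above a 1% heteroplasmy detection threshold after a
depth floor and a strand-balance error screen, matched allele-exactly
against a curated pathogenic list, and assigned maternal / de novo /
unknown inheritance from the mother's calls where a maternal sample
exists.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional

from .types import CuratedLists, MtdnaCall, MtdnaFinding

log = logging.getLogger(__name__)


@dataclass
class MtdnaQcConfig:
    """Detection threshold and error screens for mtDNA calls.

    WGS gives very high mtDNA coverage, hence the 100x depth floor.
    ``homoplasmy_cutoff`` is the heteroplasmy percentage at or above
    which a variant is reported as homoplasmic.
    """

    min_heteroplasmy: float = 1.0  # percent
    min_depth: int = 100
    require_both_strands: bool = True
    homoplasmy_cutoff: float = 95.0  # percent


def filter_mtdna_calls(
    calls: Iterable[MtdnaCall], qc: MtdnaQcConfig | None = None
) -> list[MtdnaCall]:
    """Restrict calls to those above threshold and passing error screens.

    Retained iff heteroplasmy >= the detection threshold, depth >= the
    floor, and alt reads are present on both strands (a one-strand pile
    of alt reads is the signature of a sequencing artefact).  Each
    rejection is logged with the rule that removed it.  The filter is a
    pure restriction and is idempotent.
    """
    qc = qc or MtdnaQcConfig()
    kept = []
    for c in calls:
        if c.allele_fraction < qc.min_heteroplasmy:
            log.debug("%s rejected: below %.2f%% threshold", c.hgvs, qc.min_heteroplasmy)
            continue
        if c.depth < qc.min_depth:
            log.debug("%s rejected: depth %d < %d", c.hgvs, c.depth, qc.min_depth)
            continue
        if qc.require_both_strands and (c.forward_alt_reads == 0 or c.reverse_alt_reads == 0):
            log.debug("%s rejected: strand imbalance", c.hgvs)
            continue
        kept.append(c)
    return kept


def match_pathogenic(
    calls: Iterable[MtdnaCall],
    curated: CuratedLists,
    qc: MtdnaQcConfig | None = None,
) -> list[MtdnaFinding]:
    """Allele-exact match of filtered calls against the pathogenic list."""
    qc = qc or MtdnaQcConfig()
    table = {(pos, ref, alt): (label, gene) for pos, ref, alt, label, gene in curated.pathogenic_mtdna}
    findings = []
    for c in calls:
        hit = table.get((c.position, c.ref, c.alt))
        if hit is None:
            continue
        label, gene = hit
        findings.append(
            MtdnaFinding(
                call=c,
                pathogenic_label=label,
                gene=gene,
                homoplasmic=c.allele_fraction >= qc.homoplasmy_cutoff,
            )
        )
    return findings


def mtdna_inheritance(
    finding: MtdnaFinding,
    mother_calls: Optional[Iterable[MtdnaCall]],
    qc: MtdnaQcConfig | None = None,
) -> MtdnaFinding:
    """Set maternal / de_novo / unknown inheritance on a finding.

    maternal: the mother carries the same allele at or above the
    detection threshold — or at any non-zero level below it, which is
    recorded as maternal with the ``mother_subthreshold`` flag (a very
    low-level carrier mother).  de_novo: mother sequenced, allele
    absent.  unknown: no maternal sample.
    """
    qc = qc or MtdnaQcConfig()
    if mother_calls is None:
        finding.inheritance = "unknown"
        return finding
    c = finding.call
    mother_af = 0.0
    for mc in mother_calls:
        if (mc.position, mc.ref, mc.alt) == (c.position, c.ref, c.alt):
            mother_af = max(mother_af, mc.allele_fraction)
    if mother_af >= qc.min_heteroplasmy:
        finding.inheritance = "maternal"
    elif mother_af > 0.0:
        finding.inheritance = "maternal"
        finding.mother_subthreshold = True
    else:
        finding.inheritance = "de_novo"
    return finding


def analyse_mtdna(
    proband_calls: Iterable[MtdnaCall],
    mother_calls: Optional[Iterable[MtdnaCall]],
    curated: CuratedLists,
    qc: MtdnaQcConfig | None = None,
) -> list[MtdnaFinding]:
    """Filter, match and assign inheritance for one proband."""
    qc = qc or MtdnaQcConfig()
    kept = filter_mtdna_calls(proband_calls, qc)
    findings = match_pathogenic(kept, curated, qc)
    return [mtdna_inheritance(f, mother_calls, qc) for f in findings]
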