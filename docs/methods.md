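# Methods

This note documents the rules the package implements, the defaults it
ships, what the synthetic data does and does not emulate, and the design
choices made where the design was genuinely open.

## Scope and model of the problem

The pipeline reproduces a national-cohort diagnostic workflow for
suspected mitochondrial disease on short-read WGS: family-based nuclear
small-variant calls, separate mtDNA calling at low heteroplasmy, CNV and
repeat-expansion genotypes, and structured phenotype (HPO) packets per
proband. Upstream steps — alignment, variant calling, consequence and
frequency annotation, prioritiser scoring, manual evidence curation —
are inputs, not computations: the package begins at annotated calls and
ends at per-family diagnoses and cohort summaries.

## Nuclear tiering

Tiers order variants by prior probability of being causative:

- tier 1 — loss of function (nonsense, frameshift, essential splice
  donor/acceptor) or trio-confirmed de novo missense/splice-region, in a
  green gene of an applied panel;
- tier 2 — missense / splice-region / in-frame indel in an applied panel
  gene;
- tier 3 — any other rare variant, on panel or off;
- tier 4 — population frequency above the rarity ceiling, or segregation
  inconsistent with the family history under every model tested.

Rarity ceilings default to AF < 1e-3 for monoallelic candidates and
AF < 1e-2 for biallelic ones (common rare-disease practice; the source
workflow states only "higher population frequency" for tier 4). A
missing frequency annotation is treated as AF 0 (unobserved) and
flagged. De novo status requires both parents genotyped homozygous
reference with DP ≥ 10 and GQ ≥ 20 in all three samples; singletons and
duos can never be de novo. Segregation models are dominant (no
unaffected carrier), biallelic (no unaffected homozygote; carriers
allowed) and, for X-chromosome variants only, X-linked (no unaffected
hemizygous male) — testing the X model on autosomes would make it
vacuously consistent and tier 4 by segregation unreachable. Tier 1/2
require green panel entries by default (amber admissible via
configuration). When a variant satisfies both the tier-1 and tier-2
branches the lower tier wins: tiers are ordered by causal probability.

Candidate channels beyond tiers 1/2: allele-exact (chrom, pos, ref,
alt) intersection with a ClinVar P/LP table carrying a genome-build
label that must match; the top 10 ranks of an external prioritiser's
per-proband output; and a laboratory-feedback override list which, by
design, wins over the research reanalysis (conflicts are logged).

## mtDNA analysis

Calls are retained at ≥ 1% heteroplasmy, depth ≥ 100× (WGS yields very
high mtDNA coverage) and with alt reads on both strands — a single-strand
pile is treated as an artefact. The error screens are deliberately
simple; NUMT-aware realignment is out of scope. Retained calls are
matched allele-exactly against a curated pathogenic list. The shipped
89-entry default collects well-known confirmed pathogenic variants and
is a provisional curation: users replicating a specific study should
load that study's list. Homoplasmy is reported at ≥ 95% heteroplasmy
(configurable; published tables report it qualitatively).

Inheritance per finding: maternal when the mother carries the allele at
or above the detection threshold; maternal with a sub-threshold flag
when she carries it at any non-zero level below it (preserving the
"very low level in mother" distinction); de novo when she was sequenced
and the allele is absent; unknown without a maternal sample. A mother
present in the pedigree is taken as sequenced — an empty call list means
the allele is absent, not that the sample is missing. Large-scale mtDNA
rearrangements are not detected, matching the modelled workflow.

## CNV and STR triage

CNVs are kept when the caller FILTER is PASS and the interval
(0-based half-open) overlaps ≥ 1 bp of ≥ 1 exon of a panel gene; no
minimum size is imposed and single-exon events are allowed. A call
spanning several panel genes yields one diagnosis listing every gene
hit (e.g. a contiguous cluster duplication). Copy number 0 is read as
biallelic loss; heterozygous events are classified de novo / inherited /
unknown from parental calls.

The 13 repeat loci ship published clinical thresholds in an editable
TSV (e.g. HTT full ≥ 40 with premutation 36–39; C9orf72 full ≥ 30; FXN
biallelic ≥ 66; FMR1 full ≥ 200, premutation 55–199; DMPK full ≥ 50).
The class follows the larger allele — full mutation at or above
`full_min`, premutation anywhere above `normal_max` below that,
otherwise normal — so classification is monotone in repeat count.
Causative requires a full mutation (both alleles expanded at the
recessive locus) and survives only if visual read review did not reject
the call; in synthetic data review defaults to confirmed above
threshold and not-needed below.

## ACMG evidence combining

The engine takes evidence codes as input (deriving codes from
annotations was a manual step in the modelled workflow and is an
extension point, not core). Codes participate at their intrinsic
strength or an explicit modifier. The 2015 combining rows are applied
on each side; when both the pathogenic and the benign side reach a
classification the call clamps to VUS. One generalisation: two
very-strong codes (possible only through modifiers) classify as
pathogenic. A lone PVS1 reaches no class, so PVS1 + BA1 resolves to
benign rather than conflict — clamping applies to qualifying
combinations, not to isolated codes.

## Phenotype score

A term's ancestor systems are the children of *Phenotypic abnormality*
lying on any parent path of the term (a term may map to several
systems; the root maps to none). The sectioned score sums mapped-term
points per section (each distinct term once), clamps each section at
its cap, clamps the three clinical sections jointly at 4, and clamps
the total at 12; bands are 0–1 unlikely, 2–4 possible, 5–7 probable,
≥ 8 definite. The shipped item map (1–2 points for clinical features,
2 for biochemical/imaging markers, up to 4 for muscle morphology) is a
provisional default in the spirit of the classic criteria: the banding
and total cap are fixed, but per-item weights for replication of a
given study must be loaded from that study's table. The scorer is
deterministic; inter-rater comparison is out of scope.

## Diagnosis aggregation

Only reviewed variants (those with an evidence record) can support a
diagnosis; benign/likely-benign classifications are excluded. Per gene,
the zygosity-consistent set is built from channel hits plus reviewed
rare variants in the same gene: homozygous or two-in-trans pairs are
biallelic (two heterozygous variants phased in cis from parental
genotypes reject the candidate; unphased pairs are presumed biallelic),
single variants classify as de novo, inherited-dominant, X-linked or
unknown from the pedigree. Base confidence is evidence-derived —
definite when every contributing variant is P/LP, probable for a
biallelic P/LP + VUS pair, possible otherwise — then shifted by an
optional signed per-(family, gene) clinical-review adjustment. This
adjustment exists because the modelled overall assessment weighed
phenotype fit, a manual judgement: in the published tables six of 104
families carry confidence labels that evidence alone cannot produce,
and the fixture supplies those six adjustments as part of the
transcription. Contribution (full/partial) is likewise a review input,
defaulting to full.

Routes record the channel that produced the hit, with priority
tier 1/2 > other SNV channels > CNV > STR > mtDNA when several hit the
same gene. A family counts once in the yield by its best diagnosis
(definite > probable > possible, then route priority); families with
two retained disorders are dual diagnoses and still count once.
Stratified yields (age ≤ 18 vs > 18; singleton / duo / trio-quad /
other) are compared with the two-sided exact hypergeometric test
(scipy's Fisher exact); a zero margin is an error.

## Synthetic data

The generator emulates the study conditions: 319 families mixing
singletons (0.32), duos (0.13), trios (0.46) and quads (0.09); 41%
child probands; diagnoses planted at the published route mix
(69 tier-1/2, 18 other-SNV, 8 CNV, 3 STR, 6 mtDNA per 319). Planted
families carry variant records engineered to satisfy exactly their
route's rules, with QC fields drawn well above thresholds and evidence
codes emitted to match the intended class. Background families carry
common panel-gene alleles (tier 4), rare off-panel variants without
evidence records (tier 3, unreviewed), sub-threshold or unlisted mtDNA
noise, and normal repeat genotypes — so at default settings unplanted
families yield no diagnoses by construction, and recovery of planted
diagnoses is exact. What passing these tests shows is that the rule
engines implement their definitions; it does not show robustness to
annotation errors, pipeline QC artefacts, linkage disequilibrium,
population structure or phasing ambiguity, none of which the generator
models.

The tables fixture deterministically re-creates the 104 published
diagnosed families (ages, sexes, genes, per-variant consequence and
ACMG classes, inheritance, contribution, confidence) plus 215
undiagnosed filler families. Family structures are synthesised to be
minimally consistent with each printed inheritance label (de novo ⇒
trio, maternal mtDNA ⇒ mother present, and so on); filler ages and
sexes are arbitrary, so age-stratified yields on the fixture are not
meaningful. The bundled HPO-style ontology is synthetic — real
top-level system identifiers with invented depth — because the real
ontology is far too large to ship; it is sufficient for the ancestor
and scoring logic, not for term-level fidelity.

## Numerical and degenerate-input choices

All thresholds are strict or inclusive as documented at each function;
ties in best-diagnosis selection break by route priority then ACMG
strength then gene name; all output tables sort by (family, gene,
variant key) so identical inputs yield byte-identical outputs.
Population AF survives the VCF round trip at float32 precision (htslib
stores INFO floats in 32 bits). Empty cohorts, empty packets, absent
optional inputs (ranks, review, phenotypes) and zero-margin 2×2 tables
are all defined behaviours (empty outputs, zero scores, empty channels,
and an error, respectively).

## Problem sizes

The shipped tests and the acceptance script run the full 319-family
fixture, a 319-family generated cohort, a 1,000-tuple tier-oracle
comparison, the exhaustive ≤4-code ACMG enumeration (24,158 cases) and
10,000 random score packets; together they complete in well under a
minute on one CPU, so no scaled-down variants are needed.

## Known limitations

- Evidence codes, phenotype fit and review adjustments are inputs;
  the package does not automate variant interpretation.
- The shipped pathogenic-mtDNA list, STR thresholds and score item map
  are documented provisional defaults, replaceable per study.
- X-linked logic assumes hemizygous male calls are emitted as haploid
  genotypes; mosaicism is not modelled.
- The GMC-feedback channel is a pass-through override, not a model of
  laboratory re-interpretation.
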