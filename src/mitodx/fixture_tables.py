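"""Transcription of the 104 published diagnosed families used as a fixture.

Each row records, for one diagnosed family of the source cohort, the
proband's age and sex, the diagnosis confidence and contribution, the
gene(s), the per-variant consequence class and ACMG class, and an
inheritance code that drives both the synthetic family structure and
the expected inheritance label.  Families 1-39 are mitochondrial
diagnoses (six of them mtDNA), families 40-104 non-mitochondrial.

Variant records are synthesised to be consistent with each published
row: protein-truncating descriptions map to loss-of-function
consequence classes, missense to missense, splice notation to the
splice classes; CNV, repeat-expansion and mtDNA rows route to their
own channels.

``REVIEW_ADJUSTMENT`` carries the published clinical-review judgement
for the six families whose printed confidence differs from the
evidence-derived rule (the source workflow's overall clinical
assessment weighed phenotype fit, which is an input here, not an
algorithm).
"""

from __future__ import annotations

# inheritance codes:
#   comphet      compound heterozygous, trio, parents each carry one variant
#   hom          homozygous proband, singleton
#   presumed     two heterozygous variants, parents unavailable
#   de_novo      trio-confirmed de novo heterozygous (autosomal)
#   ad           heterozygous, shared with an affected parent (duo)
#   mono_unknown heterozygous singleton
#   xlr_dn       de novo hemizygous male (X)
#   xld_dn       de novo heterozygous female (X)
#   xlr_mat      hemizygous male, inherited from unaffected carrier mother
#   cnv_dn       de novo CNV, trio
#   cnv_hom      homozygous CNV (copy number 0), singleton
#   cnv_het      heterozygous CNV, singleton
#   cnv_ad       heterozygous CNV shared with an affected parent
#   str          repeat expansion, singleton
#   mt_vlow      mtDNA, mother carries at very low (sub-threshold) level
#   mt_dn        mtDNA, absent in mother
#   mt_mat       mtDNA, maternally inherited
#   mt_unknown   mtDNA, no maternal sample

X_GENES = {"AIFM1", "PDHA1", "BCAP31", "AR", "FMR1"}

#: families whose nuclear-SNV diagnosis came through the ClinVar P/LP
#: intersect rather than the panel tiers (genes kept off the applied panels)
CLINVAR_ROUTE = {41, 42, 43, 45, 46, 52, 63, 64, 66, 69, 74, 75, 82, 83, 96, 97}
#: families routed through the external prioritiser's top-10 channel
EXOMISER_ROUTE = {102, 103}

#: published clinical-review confidence adjustments (signed steps)
REVIEW_ADJUSTMENT = {31: -1, 36: +1, 99: -1, 100: -1, 101: +1, 102: -2}

# (fid, age, sex, contribution, confidence, entries)
# entry = (gene_or_genes, kind, inheritance_code, payload)
#   kind "snv":   payload = [(consequence, acmg_class), ...]
#   kind "cnv":   payload = (cnv_type, copy_number, acmg_class)
#   kind "str":   payload = (locus, allele1, allele2, acmg_class)
#   kind "mtdna": payload = (position, ref, alt, af_percent, mother_af, acmg_class)
TABLE1 = [
    (1, 10, "F", "full", "definite", [("AARS2", "snv", "hom", [("missense", "LP")])]),
    (2, 1, "M", "full", "definite", [("AIFM1", "snv", "xlr_dn", [("inframe_indel", "P")])]),
    (3, 0, "F", "full", "definite", [(["ATAD3A", "ATAD3B"], "cnv", "cnv_dn", ("gain", 3, "P"))]),
    (4, 0, "M", "full", "definite", [(["ATAD3A", "ATAD3B"], "cnv", "cnv_dn", ("gain", 3, "P"))]),
    (5, 13, "M", "full", "definite",
     [("C12orf65", "snv", "comphet", [("frameshift", "P"), ("frameshift", "P")])]),
    (6, 6, "M", "full", "definite", [("EARS2", "snv", "hom", [("missense", "LP")])]),
    (7, 2, "F", "full", "definite",
     [("FBXL4", "snv", "comphet", [("frameshift", "P"), ("frameshift", "P")])]),
    (8, 18, "F", "full", "definite", [("HIBCH", "snv", "hom", [("missense", "LP")])]),
    (9, 22, "F", "full", "definite",
     [("KARS1", "snv", "comphet", [("missense", "P"), ("missense", "LP")])]),
    (10, 1, "F", "full", "definite", [("MRPL44", "snv", "hom", [("missense", "P")])]),
    (11, 23, "M", "full", "definite", [("MRPS25", "snv", "hom", [("missense", "LP")])]),
    (12, 42, "F", "full", "definite",
     [("MT-ATP6", "mtdna", "mt_vlow", (8618, "T", "TT", 14.0, 0.5, "P"))]),
    (13, 24, "M", "full", "definite",
     [("MT-ATP6", "mtdna", "mt_dn", (8969, "G", "A", 84.0, 0.0, "P"))]),
    (14, 26, "F", "full", "definite",
     [("MT-ND3", "mtdna", "mt_dn", (10158, "T", "C", 23.0, 0.0, "P"))]),
    (15, 67, "M", "partial", "definite",
     [("MT-ND6", "mtdna", "mt_unknown", (14484, "T", "C", 100.0, None, "P"))]),
    (16, 18, "M", "full", "definite",
     [("MT-TE", "mtdna", "mt_mat", (14674, "T", "C", 100.0, 60.0, "P"))]),
    (17, 18, "F", "partial", "definite",
     [("MT-RNR1", "mtdna", "mt_mat", (1555, "A", "G", 100.0, 100.0, "P"))]),
    (18, 10, "F", "full", "definite", [("MTO1", "snv", "hom", [("missense", "P")])]),
    (19, 13, "F", "full", "definite",
     [("NDUFAF5", "snv", "comphet", [("splice_region", "LP"), ("missense", "LP")])]),
    (20, 1, "M", "full", "definite",
     [("NDUFAF8", "snv", "comphet", [("frameshift", "P"), ("intronic", "LP")])]),
    (21, 7, "M", "full", "definite",
     [("OPA1", "snv", "comphet", [("essential_splice_acceptor", "P"), ("missense", "P")])]),
    (22, 11, "F", "full", "definite", [("PDHA1", "snv", "xld_dn", [("missense", "LP")])]),
    (23, 17, "F", "full", "definite", [("PDP1", "snv", "hom", [("nonsense", "LP")])]),
    (24, 56, "M", "full", "definite", [("POLG", "snv", "hom", [("missense", "P")])]),
    (25, 48, "F", "full", "definite", [("RRM2B", "snv", "ad", [("missense", "P")])]),
    (26, 0, "M", "full", "definite",
     [("SCO2", "snv", "comphet", [("missense", "P"), ("inframe_indel", "LP")])]),
    (27, 0, "F", "full", "definite",
     [("SCO2", "snv", "comphet", [("missense", "LP"), ("missense", "LP")])]),
    (28, 74, "F", "full", "definite", [("SLC25A4", "snv", "mono_unknown", [("missense", "P")])]),
    (29, 20, "F", "full", "definite",
     [("TTC19", "snv", "comphet", [("essential_splice_donor", "P"), ("frameshift", "LP")])]),
    (30, 66, "M", "full", "definite", [("TWNK", "snv", "mono_unknown", [("missense", "P")])]),
    (31, 61, "M", "full", "probable", [("DNM1L", "snv", "mono_unknown", [("inframe_indel", "LP")])]),
    (32, 4, "F", "full", "probable",
     [("ELAC2", "snv", "comphet", [("frameshift", "P"), ("missense", "VUS")])]),
    (33, 7, "F", "full", "probable",
     [("GFER", "snv", "comphet", [("frameshift", "P"), ("intronic", "VUS")])]),
    (34, 19, "M", "full", "probable",
     [("MTFMT", "snv", "comphet", [("missense", "P"), ("splice_region", "VUS")])]),
    (35, 4, "F", "full", "probable",
     [("RRM2B", "snv", "comphet", [("missense", "LP"), ("missense", "VUS")])]),
    (36, 3, "M", "full", "probable",
     [("SDHA", "snv", "comphet", [("missense", "VUS"), ("missense", "VUS")])]),
    (37, 18, "M", "full", "possible", [("LONP1", "snv", "de_novo", [("missense", "VUS")])]),
    (38, 0, "M", "full", "possible", [("PDHA1", "snv", "xlr_mat", [("splice_region", "VUS")])]),
    (39, 56, "M", "full", "possible",
     [("TOP3A", "snv", "presumed", [("missense", "VUS"), ("missense", "VUS")])]),
]

TABLE2 = [
    (40, 0, "F", "full", "definite", [("ACTA2", "snv", "de_novo", [("missense", "P")])]),
    (41, 42, "F", "full", "definite",
     [("AMACR", "snv", "comphet", [("frameshift", "P"), ("missense", "LP")])]),
    (42, 57, "M", "full", "definite", [("AMACR", "snv", "hom", [("missense", "P")])]),
    (43, 71, "F", "full", "definite", [("AMACR", "snv", "hom", [("missense", "P")])]),
    (44, 9, "F", "full", "definite", [("AMPD2", "snv", "hom", [("missense", "LP")])]),
    (45, 29, "M", "full", "definite", [("APP", "snv", "ad", [("missense", "P")])]),
    (46, 18, "M", "partial", "definite", [("ASL", "snv", "hom", [("missense", "P")])]),
    (47, 15, "M", "full", "definite", [("ASXL3", "snv", "de_novo", [("nonsense", "P")])]),
    (48, 15, "M", "full", "definite", [("ATP1A3", "snv", "de_novo", [("missense", "P")])]),
    (49, 86, "F", "full", "definite", [("ATP1A3", "snv", "mono_unknown", [("missense", "P")])]),
    (50, 5, "M", "full", "definite", [("ATP6V1A", "snv", "de_novo", [("missense", "LP")])]),
    (51, 1, "F", "full", "definite", [("ATXN7", "str", "str", ("ATXN7", 150, 10, "P"))]),
    (52, 44, "F", "full", "definite", [("BBS1", "snv", "hom", [("missense", "P")])]),
    (53, 2, "M", "full", "definite", [("BCAP31", "snv", "xlr_dn", [("nonsense", "P")])]),
    (54, 26, "F", "full", "definite", [("C19orf12", "snv", "mono_unknown", [("frameshift", "LP")])]),
    (55, 12, "F", "full", "definite", [("CACNA1A", "snv", "de_novo", [("missense", "LP")])]),
    (56, 2, "M", "full", "definite", [("CACNA1E", "snv", "de_novo", [("missense", "LP")])]),
    (57, 12, "M", "full", "definite", [("CTBP1", "snv", "de_novo", [("missense", "P")])]),
    (58, 11, "M", "full", "definite",
     [("DOCK6", "snv", "comphet", [("splice_region", "LP"), ("frameshift", "P")])]),
    (59, 12, "F", "full", "definite", [("DSP", "snv", "de_novo", [("missense", "LP")])]),
    (60, 8, "F", "full", "definite", [("EXOSC3", "snv", "hom", [("missense", "P")])]),
    (61, 61, "M", "partial", "definite", [("EYA4", "snv", "mono_unknown", [("nonsense", "LP")])]),
    (62, 2, "M", "full", "definite",
     [("FIG4", "snv", "comphet", [("essential_splice_acceptor", "P"), ("missense", "LP")])]),
    (63, 6, "F", "full", "definite",
     [("GCDH", "snv", "comphet", [("missense", "P"), ("missense", "LP")])]),
    (64, 3, "F", "full", "definite",
     [("HADHA", "snv", "comphet", [("missense", "P"), ("missense", "LP")])]),
    (65, 10, "F", "full", "definite", [("HK1", "snv", "de_novo", [("missense", "P")])]),
    (66, 9, "M", "full", "definite",
     [("HSD17B4", "snv", "comphet", [("frameshift", "P"), ("missense", "LP")])]),
    (67, 71, "M", "partial", "definite", [("HTT", "str", "str", ("HTT", 40, 17, "P"))]),
    (68, 7, "F", "full", "definite", [("HTT", "str", "str", ("HTT", 120, 18, "P"))]),
    (69, 41, "M", "partial", "definite", [("KCNQ4", "snv", "mono_unknown", [("missense", "P")])]),
    (70, 6, "F", "full", "definite", [("KCNT1", "snv", "de_novo", [("missense", "LP")])]),
    (71, 46, "F", "full", "definite",
     [("KIF11", "snv", "ad", [("essential_splice_acceptor", "P")])]),
    (72, 29, "M", "partial", "definite", [("KMT2C", "snv", "de_novo", [("frameshift", "P")])]),
    (73, 0, "F", "full", "definite", [("MBD5", "cnv", "cnv_het", ("loss", 1, "LP"))]),
    (74, 72, "M", "full", "definite", [("MYH2", "snv", "mono_unknown", [("missense", "P")])]),
    (75, 57, "M", "partial", "definite", [("MYH7", "snv", "mono_unknown", [("missense", "P")])]),
    (76, 13, "M", "full", "definite", [("NARS1", "snv", "de_novo", [("nonsense", "P")])]),
    (77, 19, "F", "full", "definite", [("NPHP1", "cnv", "cnv_hom", ("loss", 0, "P"))]),
    (78, 3, "M", "full", "definite", [("NPHP1", "cnv", "cnv_hom", ("loss", 0, "P"))]),
    (79, 31, "F", "partial", "definite", [("OPTN", "cnv", "cnv_het", ("loss", 1, "P"))]),
    (80, 1, "M", "full", "definite",
     [("P4HTM", "snv", "comphet", [("nonsense", "P"), ("frameshift", "P")])]),
    (81, 36, "F", "full", "definite", [("PDGFB", "cnv", "cnv_ad", ("loss", 1, "P"))]),
    (82, 11, "F", "partial", "definite",
     [("PHKB", "snv", "comphet", [("frameshift", "P"), ("intronic", "P")])]),
    (83, 3, "M", "partial", "definite", [("PKD2", "snv", "ad", [("nonsense", "P")])]),
    (84, 45, "F", "full", "definite",
     [("PMM2", "snv", "comphet", [("missense", "P"), ("missense", "LP")]),
      ("AQP2", "snv", "comphet", [("frameshift", "LP"), ("missense", "LP")])]),
    (85, 2, "F", "full", "definite",
     [("POGZ", "snv", "de_novo", [("essential_splice_acceptor", "P")])]),
    (86, 54, "F", "full", "definite",
     [("POLR3A", "snv", "comphet", [("nonsense", "P"), ("intronic", "P")])]),
    (87, 2, "M", "full", "definite", [("PPP2R5D", "snv", "de_novo", [("missense", "P")])]),
    (88, 7, "F", "full", "definite", [("SAMD9", "snv", "de_novo", [("nonsense", "LP")])]),
    (89, 24, "M", "full", "definite", [("SCN2A", "snv", "de_novo", [("missense", "LP")])]),
    (90, 49, "F", "full", "definite", [("SHOC2", "snv", "mono_unknown", [("missense", "LP")])]),
    (91, 56, "M", "partial", "definite",
     [("SLC20A2", "snv", "mono_unknown", [("frameshift", "LP")])]),
    (92, 25, "M", "full", "definite",
     [("SLC52A2", "snv", "comphet", [("missense", "P"), ("missense", "P")])]),
    (93, 11, "F", "full", "definite", [("SOS1", "snv", "de_novo", [("missense", "P")])]),
    (94, 12, "M", "partial", "definite",
     [("TAB2", "snv", "de_novo", [("essential_splice_donor", "LP")])]),
    (95, 7, "F", "full", "definite", [("TANGO2", "cnv", "cnv_hom", ("loss", 0, "P"))]),
    (96, 58, "M", "partial", "definite",
     [("TTN", "snv", "mono_unknown", [("essential_splice_donor", "P")])]),
    (97, 73, "M", "full", "definite", [("TTR", "snv", "mono_unknown", [("missense", "P")])]),
    (98, 22, "F", "full", "definite", [("ZBTB20", "snv", "mono_unknown", [("missense", "LP")])]),
    (99, 59, "F", "full", "probable", [("CTNNB1", "snv", "mono_unknown", [("frameshift", "LP")])]),
    (100, 0, "M", "full", "probable",
     [("MYBPC3", "snv", "comphet", [("frameshift", "P"), ("missense", "LP")])]),
    (101, 22, "F", "full", "probable", [("PEX16", "snv", "hom", [("missense", "VUS")])]),
    (102, 60, "F", "full", "possible",
     [("MARS1", "snv", "mono_unknown", [("inframe_indel", "LP")])]),
    (103, 52, "M", "full", "possible", [("MYH2", "snv", "mono_unknown", [("missense", "VUS")])]),
    (104, 13, "M", "full", "possible",
     [("MYO9A", "snv", "comphet", [("missense", "VUS"), ("missense", "VUS")])]),
]

ALL_ROWS = TABLE1 + TABLE2

#: nuclear genes counted as mitochondrial (the mtDNA-encoded MT-* genes
#: are always mitochondrial and need no listing)
MITO_NUCLEAR_GENES = {
    "AARS2", "AIFM1", "ATAD3A", "ATAD3B", "C12orf65", "EARS2", "FBXL4", "HIBCH",
    "KARS1", "MRPL44", "MRPS25", "MTO1", "NDUFAF5", "NDUFAF8", "OPA1", "PDHA1",
    "PDP1", "POLG", "RRM2B", "SCO2", "SLC25A4", "TTC19", "TWNK", "DNM1L",
    "ELAC2", "GFER", "MTFMT", "SDHA", "LONP1", "TOP3A",
}

#: expected inheritance enum label per inheritance code
INHERITANCE_LABEL = {
    "comphet": "biallelic",
    "hom": "biallelic",
    "presumed": "biallelic",
    "de_novo": "monoallelic_de_novo",
    "ad": "monoallelic_AD",
    "mono_unknown": "monoallelic_unknown",
    "xlr_dn": "x_linked_recessive",
    "xld_dn": "x_linked_dominant",
    "xlr_mat": "x_linked_recessive",
    "cnv_dn": "monoallelic_de_novo",
    "cnv_hom": "biallelic",
    "cnv_het": "monoallelic_unknown",
    "cnv_ad": "monoallelic_AD",
    "str": "monoallelic_unknown",
    "mt_vlow": "mtdna_maternal",
    "mt_dn": "mtdna_de_novo",
    "mt_mat": "mtdna_maternal",
    "mt_unknown": "mtdna_unknown",
}

DE_NOVO_CODES = {"de_novo", "xlr_dn", "xld_dn", "cnv_dn", "mt_dn"}

N_DIAGNOSED = 104
N_FILLER = 215
N_FAMILIES = 319
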