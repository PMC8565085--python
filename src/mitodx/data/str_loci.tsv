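# Default clinical thresholds for the 13 assessed repeat-expansion loci.
# Editable: replace with a study-specific table to reproduce other cut-offs.
# Repeat counts; premut_lo/premut_hi empty when no premutation band is defined.
locus	repeat_unit	normal_max	premut_lo	premut_hi	full_min	inheritance_mode
HTT	CAG	35	36	39	40	dominant
AR	CAG	34			38	x_linked
ATN1	CAG	35	36	47	48	dominant
ATXN1	CAG	35	36	38	39	dominant
ATXN2	CAG	31	32	32	33	dominant
ATXN3	CAG	44	45	59	60	dominant
ATXN7	CAG	33	34	36	37	dominant
CACNA1A	CAG	18	19	19	20	dominant
TBP	CAG	40	41	48	49	dominant
C9orf72	GGGGCC	23	24	29	30	dominant
FXN	GAA	33	34	65	66	recessive
FMR1	CGG	54	55	199	200	x_linked
DMPK	CTG	34	35	49	50	dominant
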