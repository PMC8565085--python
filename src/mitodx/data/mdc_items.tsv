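# Default HPO-term item map for the modified mitochondrial disease score.
# Provisional defaults derived from the classic criteria (clinical features
# 1-2 points, biochemical/imaging 1-2, muscle morphology up to 4); load a
# study-specific table to reproduce other weightings.
hpo_term	section	points
HP:0003198	clinical_muscular	2
HP:0001324	clinical_muscular	1
HP:0000602	clinical_muscular	2
HP:0003546	clinical_muscular	1
HP:0000508	clinical_muscular	1
HP:0001250	clinical_cns	1
HP:0002401	clinical_cns	2
HP:0002376	clinical_cns	2
HP:0001251	clinical_cns	1
HP:0001257	clinical_cns	1
HP:0001249	clinical_cns	1
HP:0000365	clinical_multisystem	1
HP:0001639	clinical_multisystem	1
HP:0000819	clinical_multisystem	1
HP:0004322	clinical_multisystem	1
HP:0000556	clinical_multisystem	1
HP:0000505	clinical_multisystem	1
HP:0002013	clinical_multisystem	1
HP:0003128	metabolic_imaging	2
HP:0002490	metabolic_imaging	2
HP:0002151	metabolic_imaging	2
HP:0002134	metabolic_imaging	2
HP:0001987	metabolic_imaging	1
HP:0003200	morphology	4
HP:0003688	morphology	4
HP:0011923	morphology	2
HP:0008347	morphology	2
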