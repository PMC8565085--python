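# Curated pathogenic mtDNA variant list (provisional default, 89 entries).
# Positions on the rCRS (16,569 bp). Allele-exact matching: ref/alt as called.
# This default collects well-known confirmed pathogenic variants; replace with
# a study-specific curation for replication work.
position	ref	alt	label	gene
583	G	A	MELAS	MT-TF
616	T	C	Maternal epilepsy	MT-TF
1494	C	T	Aminoglycoside-induced deafness	MT-RNR1
1555	A	G	Aminoglycoside-induced and nonsyndromic deafness	MT-RNR1
1606	G	A	Ataxia, myoclonus and deafness	MT-TV
1644	G	A	Leigh syndrome	MT-TV
3243	A	G	MELAS / maternally inherited diabetes and deafness	MT-TL1
3243	A	T	MELAS-like myopathy	MT-TL1
3256	C	T	MELAS	MT-TL1
3258	T	C	MELAS / myopathy	MT-TL1
3260	A	G	Maternal myopathy and cardiomyopathy	MT-TL1
3271	T	C	MELAS	MT-TL1
3291	T	C	MELAS	MT-TL1
3302	A	G	Mitochondrial myopathy	MT-TL1
3303	C	T	Fatal infantile cardiomyopathy	MT-TL1
3376	G	A	LHON/MELAS overlap	MT-ND1
3460	G	A	LHON	MT-ND1
3635	G	A	LHON	MT-ND1
3697	G	A	MELAS / Leigh syndrome	MT-ND1
3700	G	A	LHON	MT-ND1
3733	G	A	LHON	MT-ND1
3890	G	A	Leigh syndrome	MT-ND1
4171	C	A	LHON	MT-ND1
4298	G	A	CPEO / multisystem disease	MT-TI
4300	A	G	Maternally inherited cardiomyopathy	MT-TI
4308	G	A	CPEO	MT-TI
4450	G	A	Myopathy and diabetes	MT-TM
4681	T	C	Leigh syndrome	MT-ND2
5244	G	A	Leigh syndrome	MT-ND2
5521	G	A	Mitochondrial myopathy	MT-TW
5537	A	AT	Leigh syndrome	MT-TW
5543	T	C	Mitochondrial myopathy	MT-TW
5650	G	A	Mitochondrial myopathy	MT-TA
5690	A	G	CPEO / myopathy	MT-TN
5703	G	A	CPEO / myopathy	MT-TN
6930	G	A	Multisystem disorder	MT-CO1
7023	G	A	MELAS-like encephalopathy	MT-CO1
7445	A	G	Nonsyndromic deafness	MT-TS1
7471	C	CC	Deafness, ataxia and myoclonus	MT-TS1
7497	G	A	Mitochondrial myopathy	MT-TS1
7511	T	C	Nonsyndromic deafness	MT-TS1
8306	T	C	Myopathy	MT-TK
8313	G	A	Gastrointestinal encephalomyopathy	MT-TK
8328	G	A	Encephalomyopathy	MT-TK
8344	A	G	MERRF	MT-TK
8356	T	C	MERRF	MT-TK
8363	G	A	MERRF / deafness and cardiomyopathy	MT-TK
8528	T	C	Infantile cardiomyopathy	MT-ATP8
8618	T	TT	NARP-like nephropathy and encephalopathy	MT-ATP6
8851	T	C	Bilateral striatal necrosis	MT-ATP6
8969	G	A	Mitochondrial nephropathy / MELAS-spectrum	MT-ATP6
8993	T	G	NARP / maternally inherited Leigh syndrome	MT-ATP6
8993	T	C	NARP / maternally inherited Leigh syndrome	MT-ATP6
9035	T	C	Ataxia	MT-ATP6
9176	T	C	Leigh syndrome / FBSN	MT-ATP6
9176	T	G	Leigh syndrome	MT-ATP6
9185	T	C	Leigh syndrome / NARP	MT-ATP6
9379	G	A	Encephalopathy	MT-CO3
9478	T	C	Leigh syndrome	MT-CO3
9952	G	A	Encephalopathy	MT-CO3
10010	T	C	Encephalomyopathy	MT-TG
10044	A	G	Encephalopathy	MT-TG
10158	T	C	Leigh syndrome / stroke-like episodes	MT-ND3
10191	T	C	Leigh syndrome / epilepsy	MT-ND3
10197	G	A	Leigh syndrome / dystonia	MT-ND3
10663	T	C	LHON	MT-ND4L
11777	C	A	Leigh syndrome	MT-ND4
11778	G	A	LHON	MT-ND4
11832	G	A	Exercise intolerance	MT-ND4
12147	G	A	MERRF/MELAS overlap	MT-TH
12201	T	C	Nonsyndromic deafness	MT-TH
12258	C	A	Diabetes and deafness	MT-TS2
12315	G	A	CPEO	MT-TL2
12320	A	G	Mitochondrial myopathy	MT-TL2
13042	G	A	MELAS/LHON overlap	MT-ND5
13051	G	A	LHON	MT-ND5
13094	T	C	Ataxia / Leigh spectrum	MT-ND5
13513	G	A	MELAS / Leigh syndrome	MT-ND5
13514	A	G	MELAS / Leigh syndrome	MT-ND5
14459	G	A	LHON / dystonia	MT-ND6
14482	C	G	LHON	MT-ND6
14484	T	C	LHON	MT-ND6
14487	T	C	Leigh syndrome / dystonia	MT-ND6
14568	C	T	LHON	MT-ND6
14674	T	C	Reversible infantile respiratory chain deficiency	MT-TE
14709	T	C	Myopathy and diabetes	MT-TE
15923	A	G	Fatal infantile multisystem disorder	MT-TT
15990	C	T	Mitochondrial myopathy	MT-TP
16023	G	A	Migraine and episodic weakness	MT-TP
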