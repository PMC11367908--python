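# 14 candidate structural variants carried by both affected genomes (D1, D2) and absent from the control (NF)
sv_id	type	chrom	start	end	genes	NF	D1	D2
tbp_inv	inversion	1	1	5433	TBP	0	1	1
pitx1_del	deletion	2	137200501	137209200	PITX1	0	1	1
chr3_del	deletion	3	231801	479100	PDGFA;PRKAR1B;DNAAF5	0	1	1
srd5a2_dup	duplication	3	107856801	107907700	SRD5A2	0	1	1
shc1_dup	duplication	4	94822101	94826100	SHC1	0	1	1
rorc_dup	duplication	4	97372801	97377100	RORC	0	1	1
wnt2b_dup	duplication	4	107914901	107923000	WNT2B	0	1	1
syce3_inv	inversion	5	185339	186259	SYCE3	0	1	1
wwox_del	deletion	6	9669113	9669182	WWOX	0	1	1
ccdc85c_del	deletion	7	120582001	120616000	CCDC85C	0	1	1
nxph1_inv	inversion	9	79527380	79534749	NXPH1	0	1	1
egfr_del	deletion	9	139446401	139499300	EGFR	0	1	1
sox9_dup	duplication	12	8562001	8572600	SOX9	0	1	1
wnt6_del	deletion	15	120911501	120914400	WNT6	0	1	1
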