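# Per-site peak q-scores (-log10 of the FDR q-value) from the two ChIP
# experiments, transcribed verbatim from the published q-score table.
# group: E = reported equally detected; 5A / 5B = reported specifically or
# dominantly detected by that factor. "-" means no significant detection
# (censored below the acceptance threshold, not zero).
# columns: group	gene	site_index	q_a	q_b
group	gene	site_index	q_a	q_b
E	SGK1	1	339	328
E	SGK1	2	79	75
E	GTF2H5	1	304	288
E	BCL2L1	1	279	405
E	SLC22A5	1	403	394
E	CDKAL1	1	695	603
E	DNM2	1	463	475
E	MBP	1	303	389
E	MBP	2	13	20
E	DUSP5	1	953	1040
E	DUSP5	2	95	142
E	DUSP5	3	146	146
E	ARL4C	1	516	583
5A	NDRG1	1	285	-
5A	DNAJC6	1	283	-
5A	CBS	1	236	-
5A	PPP2R2B	1	223	-
5A	ST3GAL1	1	339	23
5A	SAMD4A	1	428	18
5A	SSH2	1	618	82
5A	MAP3K5	1	237	26
5B	DOCK8	1	-	621
5B	SNX9	1	-	535
5B	LNPEP	1	-	448
5B	SKAP1	1	-	499
5B	PTGER1	1	-	446
5B	DIDO1	1	-	416
5B	TNFSF10	1	58	633
5B	FOXP3	1	456	1006
5B	FOXP3	2	-	42
5B	IL2RA	1	-	24
5B	IL2RA	2	120	301
5B	IL2RA	3	-	22
5B	IL2RA	4	120	245
5B	IL2RA	5	74	154
5B	UGCG	1	73	949
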