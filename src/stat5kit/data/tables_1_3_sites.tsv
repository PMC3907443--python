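# Binding-site sequences and genomic spans for the 27 highlighted candidate
# genes, transcribed verbatim from the published tables (equal, STAT5A-side,
# STAT5B-side). Coordinates are 1-based inclusive as printed; chrom is the
# printed chromosome with the "Chr " prefix removed (printed typos, including
# the X entries for IL2RA sites 2-5, are preserved deliberately).
# columns: gene	site_index	table_label	sequence	chrom	start	end
gene	site_index	table_label	sequence	chrom	start	end
SGK1	1	equal	TTCCAGGAA	6	134557320	134557328
SGK1	2	equal	TTCCCCAGAA	6	13561874	13561883
GTF2H5	1	equal	TTCCAAGAA	6	158628727	158628732
BCL2L1	1	equal	TTCTAAGAA	20	30263758	30263766
SLC22A5	1	equal	TTCTTAAA	5	131732692	131732700
CDKAL1	1	equal	TTCTTGGAA	6	20534571	20534579
DNM2	1	equal	TTCCTGGAA	19	10908448	10908456
MBP	1	equal	TTCTCAGAA	18	74779503	74779511
MBP	2	equal	TTCTTGAAA	18	74814691	74814699
DUSP5	1	equal	TTCTAGGAA	10	112261216	112261224
DUSP5	2	equal	TTCCCTGAA	10	112262968	112262976
DUSP5	3	equal	TTCTTAGAA	10	112264047	112264055
ARL4C	1	equal	TTCTGAAAA	2	235399028	235399036
NDRG1	1	A-specific	TTCCTGGAA	8	134315482	134315490
DNAJC6	1	A-specific	TTCCTAGAA	1	65859207	65859215
CBS	1	A-specific	TTCCTGGAA	21	44465709	44465717
PPP2R2B	1	A-specific	TTGCTATGAA	5	146174088	146174097
ST3GAL1	1	A-dominant	TTCCAGGAA	8	134532952	134532960
SAMD4A	1	A-dominant	TTCTTGGAA	14	55240186	55240194
SSH2	1	A-dominant	TTCTCAGAA	17	28087490	28087498
MAP3K5	1	A-dominant	TTCTTGTAA	6	137072913	137072921
DOCK8	1	B-specific	TTCCTAGAA	9	237726	237734
SNX9	1	B-specific	AAGCTT	6	158281655	158281660
LNPEP	1	B-specific	TTCTCAGAA	5	96294057	96294065
SKAP1	1	B-specific	TTCATGGCAGATGAA	17	46271592	46271606
PTGER1	1	B-specific	TTAGTGGAA	14	52786605	52786613
DIDO1	1	B-specific	TCCAGGAA	20	61549907	61549914
TNFSF10	1	B-dominant	TTCCAAGAA	3	172235834	172235842
FOXP3	1	B-dominant	CAGCTCTT	X	49129970	49129981
FOXP3	2	B-dominant	TTCTAAGAA	X	49134028	49134036
IL2RA	1	B-dominant	TTCTAAGAA	10	6082278	6082286
IL2RA	2	B-dominant	ACAGTCTT	X	6087689	6087697
IL2RA	3	B-dominant	TTCAAACGAA	X	6093331	6093340
IL2RA	4	B-dominant	TTCTGAGAA	X	6100740	6100752
IL2RA	5	B-dominant	TTCTACGAA	X	6111306	6111314
UGCG	1	B-dominant	TTCTTTGAA	9	114660802	114660810
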