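# Knockdown-validation outcomes for the 27 candidate genes as reported in the
# qPCR validation figure: "A-specific" = expression fell (P<0.01) only under
# STAT5A knockdown, "B-specific" symmetric, "redundant" = fell under both,
# "none" = no significant change under either.
# columns: gene	kd_label
gene	kd_label
SGK1	redundant
GTF2H5	redundant
SLC22A5	redundant
CDKAL1	none
DNM2	none
DUSP5	none
MBP	none
ARL4C	none
NDRG1	A-specific
DNAJC6	A-specific
ST3GAL1	A-specific
SAMD4A	A-specific
SSH2	A-specific
MAP3K5	A-specific
BCL2L1	A-specific
DOCK8	B-specific
SNX9	B-specific
SKAP1	B-specific
TNFSF10	B-specific
FOXP3	B-specific
IL2RA	B-specific
UGCG	B-specific
CBS	none
PPP2R2B	none
LNPEP	none
PTGER1	none
DIDO1	none
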