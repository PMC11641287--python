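mirna_id	gene_id
hsa-miR-326-3p	SMO
hsa-miR-326-3p	NOTCH1
hsa-miR-326-3p	CCND1
hsa-miR-326-3p	SP1
hsa-miR-326-3p	GLI1
hsa-miR-326-3p	GLI2
hsa-miR-326-3p	ERBB2
hsa-miR-326-3p	NF2
hsa-miR-326-3p	KRAS
hsa-miR-326-3p	RBM47
hsa-miR-326-3p	ARRDC1
hsa-miR-326-3p	GYS1
hsa-miR-145-5p	PARP8
hsa-miR-145-5p	IRS1
hsa-miR-145-5p	MYC
hsa-miR-145-5p	FSCN1
hsa-miR-145-5p	VEGFA
hsa-miR-145-5p	KDR
hsa-miR-145-5p	ANGPT1
hsa-miR-145-5p	HIF1A
hsa-miR-145-5p	NRP1
hsa-miR-145-5p	FLT1
hsa-miR-145-5p	SMAD2
hsa-miR-145-5p	SMAD3
hsa-miR-99a	CCND2
hsa-miR-99a	GRB2
hsa-miR-99a	MCM4
hsa-miR-99a	LAMTOR1
hsa-miR-99a	RPS6
hsa-miR-99a	CDK6
hsa-miR-99a	E2F1
hsa-miR-99a	CDC20
hsa-miR-99a	CCNE1
hsa-miR-99a	MCM2
hsa-miR-99a	ATM
hsa-miR-99a	CHEK1
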