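Hedgehog signaling	synthetic stand-in set	SMO	NOTCH1	CCND1	SP1	GLI1	GLI2	PTCH1	SUFU	KIF7	HHIP
NF-kB signaling	synthetic stand-in set	ERBB2	NF2	KRAS	RBM47	RELA	NFKB1	IKBKB	TRAF6	MYD88	TNFAIP3
TGF-beta signaling	synthetic stand-in set	IRS1	MYC	SMAD2	SMAD3	TGFBR1	TGFBR2	SMAD4	GRB2	RPS6	SKP1
angiogenesis	synthetic stand-in set	FSCN1	VEGFA	KDR	ANGPT1	HIF1A	NRP1	FLT1	TEK	PDGFB	FGF2
cell cycle	synthetic stand-in set	CCND2	MCM4	CDK6	E2F1	CDC20	CCNE1	CDK4	RB1	MCM2	ORC1
DNA damage response	synthetic stand-in set	ATM	CHEK1	RAD51	ATR	BRCA1	BRCA2	CHEK2	MDC1	TP53BP1	H2AX
pathways in cancer	synthetic stand-in set	MYC	KRAS	CCND1	ERBB2	NOTCH1	VEGFA	TP53	PTEN	PIK3CA	AKT1
olfactory transduction	synthetic decoy set	OR1A1	OR2B6	OR5P2	OR7C1	OR10A4	ADCY3	GNAL	CNGA2	CNGB1	RTP1
cardiac muscle contraction	synthetic decoy set	MYH6	MYH7	TNNT2	TNNI3	ACTC1	TPM1	MYL2	MYL3	RYR2	ATP2A2
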