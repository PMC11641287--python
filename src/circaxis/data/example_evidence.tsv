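parent_gene_id	gene_p	gene_direction	circ_id	circ_direction	circ_p	circ_log2fc	mirna_id	mirna_direction	context_percentile	mirna_p	mirna_log2fc	km_p	km_worse_group
FUK	0.00024094	down	hsa_circ_0002599	down	0.00008	-0.901	hsa-miR-326-3p	up	99	0.0283	2.7	0.033	high
PAPPA	0.0047841	down	hsa_circ_0088251	down	0.0001	-0.758	hsa-miR-326-3p	up	86	0.0283	2.7	0.033	high
COL1A1	1.62437e-12	up	hsa_circ_0044556	up	0.00013	1.275	hsa-miR-145-5p	down	72	0.0000006	-3.40	0.051	low
FAM120A	4.5878e-06	up	hsa_circ_0001875	up	0.000225	1.798	hsa-miR-145-5p	down	73	0.0000006	-3.40	0.051	low
TMEM165	1.62437e-12	up	hsa_circ_0001414	up	0.000368	1.130	hsa-miR-99a	down	87	0.0000065	-3.42	0.000011	low
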