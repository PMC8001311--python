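s_no	position	edited_site	gene_id	eff_d12	eff_d20	encoded_protein
1	14198871	5' UTR	AT2G16586	77.30	65.74	Transmembrane protein
2	16918673	CDS	AT5G42320	24.20	0	Zn-dependent exopeptidase superfamily protein
3	603074	5' UTR	AT5G02670	0	22.80	Hypothetical protein
4	7191297	3' UTR	AT3G41768	45.54	49.65	Ribosomal RNA
5	15653919	3' UTR	AT4G32430	0	20.43	PPR-like superfamily protein
6	17708862	3' UTR	AT3G47965	24.54	22.48	Hypothetical protein
7	21320395	CDS	AT5G52530	20.65	0	Dentin sialophosphoprotein-like protein
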