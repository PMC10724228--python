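name	abbreviation	smiles	W_film	TOC	V_water	M_c	S_film	value
Poly(isopropyl acrylate)	PIPA	*CC(*)C(=O)OC(C)C	34.1	0.5705	62	63.16	7.48	0.0002196
Poly(isodecyl acrylate)	PIDA	*CC(*)C(=O)OCCCCCCCC(C)C	16.1	0.5347	57	73.58	8.46	0.0003041
Poly(benzyl acrylate)	PBA	*CC(*)C(=O)OCc1ccccc1	19.4	0.749	47	74.07	6.63	0.0003695
Poly(2-methoxyethyl acrylate)	PMEA	*CC(*)C(=O)OCCOC	12.6	0.5426	68	55.38	12.60	0.0004196
Poly(2-butoxyethyl acrylate)	PBEA	*CC(*)C(=O)OCCOCCCC	9.9	0.7745	50	62.79	14.00	0.0004450
Poly(vinyl butyral)	PVB	*CC1CC(*)OC(CCC)O1	11	0.6276	50	67.61	7.20	0.0005861
Poly(hexamethylene sebacate)	PHMS	*CCCCCCOC(=O)CCCCCCCCC(=O)O*	8.8	0.4898	76	67.61	9.69	0.0006457
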