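name	abbreviation	smiles	value
Polystyrene	PS	*CC(*)c1ccccc1	0.006566
Polypropylene	PP	*CC(*)C	0.02008
Polyacetal	POM	*CO*	0.02129
Poly(tetrafluoroethylene)	PTFE	*C(*)(F)F	0.02782
Polycarbonate	PC	*Oc1ccc(C(C)(C)c2ccc(OC(*)=O)cc2)cc1	0.0284
Poly(methyl methacrylate)	PMMA	*CC(*)(C)C(=O)OC	0.04292
Poly(ethylene naphthalate)	PEN	*CCOC(=O)c1ccc2cc(C(=O)O*)ccc2c1	0.2101
Polychloroprene	CR	*CC/C=C(/*)Cl	0.4655
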