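name	abbreviation	smiles	value
Poly(ethylene terephthalate)	PET	*CCOC(=O)c1ccc(C(=O)O*)cc1	0.0003
Poly(lactic acid)	PLA	*OC(C)C(=O)*	0.00033
Poly(L-lactic acid)	PLLA	*C([C@H](O*)C)=O	0.0014
Polycaprolactone	PCL	*CCCCCC(=O)O*	0.0027
Polystyrene	PS	*CC(*)c1ccccc1	0.0111
Polyurethane	PU	*C(=O)NC1=CC=C(CC2=CC=C(NC(=O)OCCO*)C=C2)C=C1	0.0116
Nylon6	Nylon6	*NCCCCCC(*)=O	0.0222
Polycarbonate	PC	*Oc1ccc(C(C)(C)c2ccc(OC(*)=O)cc2)cc1	0.0238
Poly(butylene succinate)	PBS	*OCCCCOC(=O)CCC(*)=O	0.0714
Nylon66	Nylon66	*NCCCCCCNC(=O)CCCCC(*)=O	0.0778
Poly(ethylene sebacate)	PESeb	*OCCOC(=O)CCCCCCCCC(*)=O	0.0894
Poly(butylene sebacate)	PBSeb	*OCCCCOC(=O)CCCCCCCCC(*)=O	0.114
Poly(butylene azelate)	PBAz	*OCCCCOC(=O)CCCCCCCC(*)=O	0.2011
Poly(3-hydroxybutyrate)	P3HB	CC(CC(*)=O)O*	0.2917
Poly(ethylene azelate)	PEAz	*OCCOC(=O)CCCCCCCC(*)=O	0.3073
Poly(butylene adipate)	PBAdip	*OCCCCOC(=O)CCCCC(*)=O	0.3929
Nylon4	Nylon4	*NCCCC(*)=O	1.4286
Poly(propylene succinate)	PPS	*OCCCOC(=O)CCCCCCC(=O)*	2.2405
Poly(vinyl alcohol)	PVA	C(C(O)*)*	2.8333
Poly(propylene azelate)	PPAz	*OCCCOC(=O)CCCCCCCC(=O)*	7.4969
Poly(propylene sebacate)	PPSeb	*OCCCOC(=O)CCCCCCCCC(*)=O	7.5642
Poly(propylene adipate)	PPAd	*OCCCOC(=O)CCCCC(=O)*	61.3197
Poly(propylene glutarate)	PPGI	*OCCCOC(=O)CCCC(=O)*	100
Poly(propylene pimalate)	PPPIM	*OCCCOC(=O)CCCCCC(*)=O	100
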