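IFN_I_Aybey	type-I interferon (IFN-a/b common) response signature	CMPK2	DDX58	GMPR	HERC5	HERC6	HRASLS2	HSH2D	IFI27	IFI6	IFIT1	IFIT3	ISG15	LAMP3	MX1	MX2	OAS1	OAS2	OASL	RSAD2	USP18
IFNb_Aybey	IFN-b response signature (IFN-a genes removed)	BST2	BTC	C3AR1	CD7	CYP2J2	DDX60L	DHX58	DLL1	GCH1	IFI44	IFI44L	IFIH1	IFIT1B	IL22RA1	IL4I1	IRF7	ISG20	LGALS9	LMO2	MMP13	MYD88	NOD2	OAS3	PDGFRL	PLSCR1	PNPT1	PPM1K	RTP4	SAMD9	SIDT1	SLFN12L	SSTR2	STARD5	THEMIS2	TLR3	TMEM229B	TNFSF13B	TRANK1	TSPAN33	ZBP1
IFN_II_Aybey	type-II interferon (IFN-g) response signature	CD74	CXCL9	GBP2	ICAM1	IDO1	IRF1
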