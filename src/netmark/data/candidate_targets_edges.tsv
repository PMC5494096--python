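mirna_id	gene_id
miR-145-5p	MMP12
miR-145-5p	ZFP36
miR-145-5p	KLF4
miR-204-5p	DPYSL2
miR-204-5p	EMP1
miR-204-5p	SPDEF
miR-204-5p	LMO7
miR-204-5p	SLC1A1
miR-204-5p	ALPL
miR-204-5p	MMP9
miR-204-5p	FRAS1
miR-182-5p	CAMK2N1
miR-182-5p	ZFP36
miR-182-5p	UBE2T
miR-182-5p	LPHN2
miR-182-5p	RGS17
miR-567	SPTBN1
miR-567	DUSP1
miR-567	BCHE
miR-567	LPHN2
miR-141-3p	H3F3B
miR-141-3p	TCEAL2
miR-141-3p	MYH10
miR-141-3p	LHFP
miR-141-3p	LPHN2
miR-141-3p	CCL2
miR-141-3p	KLF9
miR-454-3p	DPYSL2
miR-454-3p	HOXA5
miR-454-3p	FKBP11
miR-454-3p	SRPX
miR-454-3p	EDN1
miR-454-3p	LDLR
miR-454-3p	CAV2
miR-454-3p	BMPR2
miR-454-3p	SLC2A1
miR-590-3p	SERPINE2
miR-590-3p	PLEKHC1
miR-590-3p	SPTBN1
miR-590-3p	H3F3B
miR-590-3p	TMEM47
miR-590-3p	TIMP3
miR-590-3p	COL3A1
miR-590-3p	CXCL13
miR-590-3p	ETS2
miR-590-3p	CELSR3
miR-590-3p	LPL
miR-590-3p	SMAD6
miR-590-3p	BMPR2
miR-590-3p	LPHN2
miR-590-3p	SASH1
miR-338-3p	COL1A1
miR-338-3p	FOSB
miR-338-3p	ADAMTS1
miR-338-3p	MMP9
miR-139-5p	FOS
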