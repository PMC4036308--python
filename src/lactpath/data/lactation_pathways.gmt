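mammary_development	64 genes, lactation pathway	ADAM17	AREGB	BMP4	BMPR1A	CSN2	CCND1	DKK1	EDAR	EGF	EGFR	ESR1	FGF1	FGF10	FGFR1	GH1	GHR	GLI2	GLI3	IGF1	IGF1R	IRS1	IRS2	LEF1	MFGE8	MMP14	MMP2	MMP3	MMP9	MSX1	MSX2	NRG1	NRG3	NTN1	PGR	PCBD1/TCF1	PRL	PRLR	PTHLH	PTH1R	PTH	TNFRSF11A	TNFSF11	RELN	SIRPA	SLIT2	SOCS1	SOCS2	SOCS3	STAT5A	STAT5B	TBX2	TBX3	TCF3	TCF4	TGFA	TGFB1	TGFBR1	TGFBR2	WAP	WNT10B	WNT11	WNT3	WNT5A	WNT6
prolactin_signalling	27 genes, lactation pathway	AKT2	CSN1S1	CSN2	CISH	RAF1	ELF5	ERBB4	ESR1	GAL	GATA3	IGF2	IL6	IRS1	JAK2	NR3C1	PRL	PRLR	PTH	SOCS1	SOCS2	SOCS3	GH1	STAT3	STAT5A	STAT5B	TNFRSF11A	TNFSF11
involution	40 genes, lactation pathway	AKT1	ATF4	BAK1	BAX	BCL2L1	CASP3	CEBPA	CEBPD	CEBPG	CISH	CTNNA1	CTNNA2	E2F1	FOXO3	IGFBP5	IL11	IL6	IL6ST	IRF1	JAK1	JAK2	LEF1	LIF	LIFR	MMP2	MMP3	MMP9	MYC	OSM	OSMR	TP53	PTEN	PTK2	RAF1	SFRP4	SOCS3	STAT3	STAT5A	STAT5B	TIMP3
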