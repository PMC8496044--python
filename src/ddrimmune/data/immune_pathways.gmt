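INTERFERON_GAMMA_RESPONSE	Genes induced by interferon gamma signaling	STAT1	STAT2	IRF1	IRF7	GBP1	GBP2	GBP4	CXCL9	CXCL10	CXCL11	IDO1	HLA-A	HLA-B	HLA-DRA	HLA-DMA	B2M	TAP1	TAP2	PSMB8	PSMB9	SOCS1	IFI35	UBE2L6	NLRC5
INTERFERON_ALPHA_RESPONSE	Type I interferon stimulated genes	IFI6	IFI27	IFI44	IFI44L	ISG15	MX1	MX2	OAS1	OAS2	OAS3	IFIT1	IFIT2	IFIT3	IRF9	RSAD2	USP18	STAT2	IFITM1	IFITM3	BST2
INFLAMMATORY_RESPONSE	Acute inflammatory signaling and leukocyte recruitment	IL1A	IL1B	IL6	CXCL8	TNF	CCL2	CCL5	CCL20	NFKB1	PTGS2	TLR2	TLR4	NLRP3	CD14	SELE	ICAM1	VCAM1	CXCL1	CXCL2	IL18
TNFA_SIGNALING_VIA_NFKB	NF-kB-dependent transcriptional response to TNF	TNF	NFKB1	NFKB2	RELA	RELB	REL	TNFAIP3	NFKBIA	NFKBIE	JUN	JUNB	FOS	FOSB	IER3	SOD2	BIRC3	TRAF1	CD83	PLAU
IL6_JAK_STAT3_SIGNALING	IL-6 family cytokine signaling through JAK/STAT3	IL6	IL6R	IL6ST	JAK1	JAK2	STAT3	SOCS3	OSMR	LIFR	CSF2RB	IL10RB	IL4R	MYD88	PIM1	CCR1
COMPLEMENT_CASCADE	Classical and alternative complement activation	C1QA	C1QB	C1QC	C1R	C1S	C2	C3	C4A	C4B	C5	C7	CFB	CFD	CFH	CFI	SERPING1	CD55	CD46	CD59	CR1
ANTIGEN_PRESENTATION	MHC class I and II antigen processing and presentation	HLA-A	HLA-B	HLA-C	HLA-DRA	HLA-DRB1	HLA-DPA1	HLA-DPB1	HLA-DQA1	HLA-DQB1	B2M	TAP1	TAP2	TAPBP	PSMB8	PSMB9	CIITA	CD74	CALR	PDIA3
T_CELL_CYTOTOXICITY	Effector molecules of cytotoxic lymphocytes	GZMA	GZMB	GZMH	GZMK	GZMM	PRF1	GNLY	NKG7	KLRD1	KLRK1	FASLG	IFNG	CTSW	CST7
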