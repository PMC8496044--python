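MISMATCH_REPAIR	Recognition and repair of base-base mismatches and insertion/deletion loops	MLH1	MLH3	MSH2	MSH3	MSH6	PMS1	PMS2	EXO1	PCNA	RFC1	RFC2	RFC3	RFC4	RFC5	LIG1	POLD1	POLD2	POLD3	POLD4	RPA1	RPA2	RPA3
BASE_EXCISION_REPAIR	Excision and replacement of damaged or inappropriate bases	OGG1	UNG	SMUG1	MBD4	TDG	MUTYH	NTHL1	NEIL1	NEIL2	NEIL3	APEX1	APEX2	POLB	LIG3	XRCC1	PARP1	PARP2	FEN1	PNKP	HMGB1	POLE	LIG1
NUCLEOTIDE_EXCISION_REPAIR	Removal of bulky helix-distorting lesions	XPA	XPC	ERCC1	ERCC2	ERCC3	ERCC4	ERCC5	ERCC6	ERCC8	DDB1	DDB2	RAD23A	RAD23B	CETN2	GTF2H1	GTF2H2	GTF2H3	GTF2H4	GTF2H5	CDK7	CCNH	MNAT1	RPA1	RPA2	LIG1	POLD1	POLE
HOMOLOGOUS_RECOMBINATION	Error-free repair of double-strand breaks using a homologous template	RAD51	RAD51B	RAD51C	RAD51D	RAD52	RAD54L	RAD54B	BRCA1	BRCA2	XRCC2	XRCC3	MRE11	RAD50	NBN	RBBP8	BARD1	PALB2	BLM	TOP3A	RMI1	RMI2	EME1	MUS81	GEN1	SLX1A	SLX4
NON_HOMOLOGOUS_END_JOINING	Direct religation of double-strand break ends	XRCC4	XRCC5	XRCC6	PRKDC	LIG4	NHEJ1	DCLRE1C	POLL	POLM	PAXX	TP53BP1	APLF	PNKP	WRN	RIF1
HOMOLOGOUS_DNA_PAIRING_AND_STRAND_EXCHANGE	RAD51-mediated presynaptic filament homology search and strand invasion	RAD51	RAD51B	RAD51C	RAD51D	XRCC2	XRCC3	RAD54L	RAD54B	BRCA2	PALB2	RAD51AP1	SWI5	SFR1	SWSAP1	ZSWIM7	PSMC3IP	MND1	DMC1
PRESYNAPTIC_PHASE_OF_HOMOLOGOUS_RECOMBINATION	End resection and RPA loading preceding RAD51 filament formation	RPA1	RPA2	RPA3	RAD51	BRCA2	PALB2	BRCA1	BARD1	RBBP8	MRE11	RAD50	NBN	EXO1	DNA2	BLM	WRN
RESOLUTION_OF_D_LOOP_STRUCTURES	Dissolution and resolution of recombination intermediates	BLM	TOP3A	RMI1	RMI2	GEN1	MUS81	EME1	EME2	SLX1A	SLX4	RAD54L	POLD1	POLD2	POLD3
PROCESSING_OF_DNA_DOUBLE_STRAND_BREAK_ENDS	Nucleolytic resection and end protection at double-strand breaks	MRE11	RAD50	NBN	RBBP8	EXO1	DNA2	BLM	WRN	BRCA1	BARD1	TP53BP1	RIF1	SHLD1	SHLD2	SHLD3	MAD2L2
DNA_DOUBLE_STRAND_BREAK_RESPONSE	Chromatin signaling cascade at double-strand breaks	ATM	H2AX	MDC1	RNF8	RNF168	UIMC1	ABRAXAS1	BRCC3	BABAM1	BABAM2	TP53BP1	BRCA1	CHEK2	KAT5	TRIM28
FANCONI_ANEMIA_PATHWAY	Interstrand crosslink sensing and FANCD2/FANCI monoubiquitination	FANCA	FANCB	FANCC	FANCD2	FANCE	FANCF	FANCG	FANCI	FANCL	FANCM	BRCA2	BRIP1	PALB2	RAD51C	SLX4	ERCC4	UBE2T	FAAP100	FAAP24
TRANSLESION_SYNTHESIS	Damage-tolerant DNA synthesis across lesions	POLH	POLI	POLK	REV1	REV3L	MAD2L2	POLN	PCNA	RAD18	UBE2A	UBE2B	HLTF	SHPRH	SPRTN
DIRECT_REVERSAL_OF_DNA_DAMAGE	Enzymatic reversal of alkylation damage without excision	MGMT	ALKBH1	ALKBH2	ALKBH3	ASCC1	ASCC2	ASCC3
INTERSTRAND_CROSSLINK_REPAIR	Unhooking and replication-coupled repair of interstrand crosslinks	FANCD2	FANCI	ERCC1	ERCC4	DCLRE1A	DCLRE1B	REV1	REV3L	POLN	RPA1	RAD51	BRCA2	FAN1	UHRF1
DNA_REPLICATION	Replisome assembly and semiconservative DNA synthesis	POLA1	POLA2	PRIM1	PRIM2	POLD1	POLD2	POLD3	POLE	POLE2	MCM2	MCM3	MCM4	MCM5	MCM6	MCM7	CDC45	GINS1	GINS2	GINS3	GINS4	PCNA	RFC1	FEN1	LIG1	RPA1	RPA2
REPLICATION_FORK_PROTECTION	Stabilization and remodeling of stalled replication forks	ATR	ATRIP	CLSPN	TIMELESS	TIPIN	WRNIP1	SMARCAL1	ZRANB3	HLTF	RAD51	BRCA1	BRCA2	BOD1L1	MCM8	MCM9
ATM_SIGNALING	ATM kinase activation and substrate phosphorylation after double-strand breaks	ATM	CHEK2	TP53	MDM2	MDC1	H2AX	RNF8	RNF168	KAT5	NBN	MRE11	RAD50	TP53BP1
ATR_ACTIVATION	ATR-ATRIP recruitment to RPA-coated single-stranded DNA and checkpoint firing	ATR	ATRIP	TOPBP1	CLSPN	RAD17	RAD9A	RAD9B	RAD1	HUS1	CHEK1	RPA1	RPA2	ETAA1	CEP164
G2_M_DNA_DAMAGE_CHECKPOINT	Damage-dependent arrest at the G2/M transition	CHEK1	CHEK2	WEE1	PKMYT1	CDC25A	CDC25B	CDC25C	CCNB1	CDK1	PLK1	YWHAE	SFN	TP53	ATM	ATR
G1_S_DNA_DAMAGE_CHECKPOINT	p53/p21-mediated arrest at the G1/S transition	TP53	CDKN1A	MDM2	MDM4	CCNE1	CDK2	RB1	E2F1	ATM	CHEK2	CDC25A
P53_DAMAGE_RESPONSE	p53-dependent transcriptional response to genotoxic stress	TP53	MDM2	MDM4	CDKN1A	BAX	BBC3	PMAIP1	GADD45A	SFN	RRM2B	SESN1	SESN2	TP53I3	ZMAT3
SANITIZATION_OF_NUCLEOTIDE_POOLS	Hydrolysis of damaged nucleotides before incorporation	NUDT1	NUDT15	NUDT18	DUT	ITPA	SAMHD1	DCTPP1
TELOMERE_MAINTENANCE	Telomerase and shelterin-mediated chromosome end protection	TERT	TERF1	TERF2	TINF2	POT1	ACD	TERF2IP	RTEL1	DKC1	WRAP53	TEN1	CTC1	STN1
SINGLE_STRAND_BREAK_REPAIR	Detection and ligation of single-strand breaks	XRCC1	LIG3	PARP1	PNKP	APTX	TDP1	TDP2	POLB	APEX1	PARG
MICROHOMOLOGY_MEDIATED_END_JOINING	Polymerase-theta-dependent alternative end joining	POLQ	PARP1	LIG1	LIG3	XRCC1	MRE11	RBBP8	NBN	FEN1
DNA_DAMAGE_UBIQUITIN_SIGNALING	Ubiquitin-dependent signal amplification at damage sites	RNF8	RNF168	UBE2N	HERC2	RNF4	PIAS1	PIAS4	USP3	USP16	BRCA1	BARD1	UIMC1
TRANSCRIPTION_COUPLED_NUCLEOTIDE_EXCISION_REPAIR	Repair of lesions blocking elongating RNA polymerase II	ERCC6	ERCC8	UVSSA	XPA	ERCC1	ERCC2	ERCC3	ERCC4	ERCC5	POLR2A	XAB2	MNAT1
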