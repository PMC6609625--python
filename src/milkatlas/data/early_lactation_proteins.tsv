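no	gene_name	protein_id	protein_name	fraction_localization	refs
1	ABCC4	A0JND8_BOVIN	ABCC4 protein	MFGM	R10
2	ACAT1	THIL_BOVIN	Acetyl-CoA acetyltransferase, mitochondrial	Skimmed	R13;R17
3	ALDH3B1	AL3B1_BOVIN	Aldehyde dehydrogenase family 3 member B1	MFGM	R10
4	ALOX12	Q6SYC4_BOVIN	Arachidonate 12-lipoxygenase	MFGM	R10
5	ARL6IP5	PRAF3_BOVIN	PRA1 family protein 3	Skimmed	R13;R17
6	ATP5F1	AT5F1_BOVIN	ATP synthase F(0) complex subunit B1, mitochondrial	Skimmed	R13;R17
7	ATP5H	ATP5H_BOVIN	ATP synthase subunit d, mitochondrial	Skimmed	R13;R17
8	ATP5J	ATP5J_BOVIN	ATP synthase-coupling factor 6, mitochondrial	Skimmed	R13;R17
9	ATP5J2	ATPK_BOVIN	ATP synthase subunit f, mitochondrial	Skimmed	R13;R17
10	BAT1	Q861P7_BOVIN	HLA-B-associated transcript 1	Skimmed	R13
11	Bt.64131	F1MIR4	RAB2A, member RAS oncogene family	MFGM	R10
12	C13H20ORF116	Q1LZB0_BOVIN	Chromosome 20 open reading frame 116 ortholog	Skimmed	R13
13	C1QBP	C1QBP_BOVIN	Complement component 1 Q subcomponent-binding protein, mitochondrial	Skimmed	R13;R17
14	CAT	CATA_BOVIN	Catalase	Skimmed	R13;R17
15	COPG	Q0V888_BOVIN	Coatomer protein complex, subunit gamma 1	Skimmed	R13;R17
16	COX5A	COX5A_BOVIN	Cytochrome c oxidase subunit 5A, mitochondrial	Skimmed	R13;R17
17	COX5B	COX5B_BOVIN	Cytochrome c oxidase subunit 5B, mitochondrial	Skimmed	R13;R17
18	COX7A2	CX7A2_BOVIN	Cytochrome c oxidase subunit 7A2, mitochondrial	Skimmed	R13;R17
19	CUZD1	F1MD73	Uncharacterized protein	MFGM	R10
20	DDRGK1	DDRGK_BOVIN	DDRGK domain-containing protein 1	Skimmed	R13;R17
21	DDX39B	DX39B_BOVIN	Spliceosome RNA helicase DDX39B	Skimmed	R17
22	EEF1B	EF1B_BOVIN	Elongation factor 1-beta	Skimmed	R13;R17
23	GPAM	GPAT1_BOVIN	Glycerol-3-phosphate acyltransferase 1, mitochondrial	MFGM	R10
24	HIST1H4A	P62803	Histone 4	MFGM	R10
25	IG	A5D7Q2	Uncharacterized protein	MFGM	R10
26	IVD	IVD_BOVIN	Isovaleryl-CoA dehydrogenase, mitochondrial	Skimmed	R13;R17
27	LF	Q95M55_BOVIN	Lactoferrin	MFGM	R10
28	LMAN1	Q8MJ82_BOVIN	Lectin mannose binding 1	Skimmed	R13;R17
29	LOC789567	A6H7H3_BOVIN	LOC789567 protein	Skimmed	R13;R17
30	LRPAP1	Q148K7_BOVIN	Low density lipoprotein receptor-related protein associated protein 1	Skimmed	R13;R17
31	LRRC59	LRC59_BOVIN	Leucine-rich repeat-containing protein 59	Skimmed	R13;R17
32	Man8	O78186_BOVIN	MHC class I antigen	MFGM	R10
33	MGC137099	Q2KII3_BOVIN	Hepatitis A virus cellular receptor 1 N-terminal domain containing protein	MFGM	R10
34	MYCBP	MYCBP_BOVIN	c-Myc-binding protein	Skimmed	R13;R17
35	NDUFA5	NDUA5_BOVIN	NADH dehydrogenase [ubiquinone] 1 alpha subcomplex subunit 5	Skimmed	R13;R17
36	NDUFAB1	ACPM_BOVIN	Acyl carrier protein, mitochondrial	Skimmed	R13;R17
37	OSTC	OSTC_BOVIN	Oligosaccharyltransferase complex subunit OSTC	Skimmed	R13
38	PAFAH1B2	PA1B2_BOVIN	Platelet-activating factor acetylhydrolase IB subunit beta	Skimmed	R13;R17
39	PCK2	F1MDS3_BOVIN	Phosphoenolpyruvate carboxykinase 2, mitochondrial	Skimmed	R13;R17
40	PLSCR2	PLS2_BOVIN	Phospholipid scramblase 2	MFGM	R10
41	RPL10A	RL10A_BOVIN	60S ribosomal protein L10a	Skimmed	R13;R17
42	RPL18	RL18_BOVIN	60S ribosomal protein L18	Skimmed;MFGM	R10;R13;R17
43	RPL6	RL6_BOVIN	60S ribosomal protein L6	Skimmed	R13;R17
44	RPL7	RL7_BOVIN	60S ribosomal protein L7	Skimmed	R13;R17
45	RPL7A	RL7A_BOVIN	60S ribosomal protein L7a	Skimmed	R13;R17
46	RPS13	RS13_BOVIN	40S ribosomal protein S13	Skimmed	R13;R17
47	SAA	P35541	Serum amyloid A protein	MFGM	R10
48	SDHA	SDHA_BOVIN	Succinate dehydrogenase [ubiquinone] flavoprotein subunit, mitochondrial	Skimmed	R13;R17
49	SEC. 11C	Q2KI36_BOVIN	Signal peptidase complex catalytic subunit SEC. 11	Skimmed	R13;R17
50	SEC. 61A1	S61A1_BOVIN	Protein transport protein Sec. 61 subunit alpha isoform 1	Skimmed	R13;R17
51	SLC15A2	B8Y6C2_BOVIN	Solute carrier family 15 member 2	MFGM	R10
52	SSR1	SSRA_BOVIN	Translocon-associated protein subunit alpha	Skimmed	R13;R17
53	SURF4	SURF4_BOVIN	Surfeit locus protein 4	Skimmed	R13;R17
54	SYPL1	A8PVV5_BOVIN	SYPL1 protein	Skimmed	R13;R17
55	TMED9	TMED9_BOVIN	Transmembrane emp24 domain-containing protein 9	Skimmed	R13;R17
56	TMEM43	A6QQR5_BOVIN	TMEM43 protein	Skimmed	R13;R17
57	TREM1	TREM1_BOVIN	Triggering receptor expressed on myeloid cells 1	Skimmed	R13;R17
58	TXNDC4	TXND4_BOVIN	Thioredoxin domain-containing protein 4	Skimmed	R13
59	UQCRC1	QCR1_BOVIN	Cytochrome b-c1 complex subunit 1, mitochondrial	Skimmed	R13;R17
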