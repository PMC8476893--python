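rank	gene_a	gene_b
1	ABCC5	FUT8
2	EFNA1	CDKN3
3	AGRN	UBE2L6
4	SLC17A9	SUPT7L
5	EPS8L2	PARN
6	ITGA3	MIS18BP1
7	ZP1	LTA
8	CRY2	RHOBTB1
9	SESTD1	CCDC25
10	GOT1	WASHC3
11	NPHP4	WDCP
12	DHFR2	NME7
13	EHBP1L1	LPCAT2
14	IWS1	TSEN15
15	USP19	HENMT1
16	ECSIT	COA8
17	AMBRA1	SOCS4
18	GLYCTK	ERP27
19	EBF1	ARHGEF39
20	MIER3	GSTT1
21	MICAL1	ZNF92
22	ZNF460	WDR66
23	PRELID2	PRMT5
24	DCAF1	TBC1D5
25	PRRC1	PPP1R2
26	STRIP1	KIN
27	GLYAT	DKK4
28	FZD9	CXCL11
29	TUBB2A	NENF
30	PRKCZ	TIMM9
31	BPNT1	TMEM39B
32	ASPHD1	THAP1
33	SLC17A9	APOL2
34	DHFR2	LPCAT2
35	KMT2B	AJUBA
36	LHFPL2	COA8
37	SFI1	DCP1B
38	DCTPP1	ENY2
39	HAGHL	KLHDC9
40	CRTC1	GSTT1
41	ASPHD1	SMUG1
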