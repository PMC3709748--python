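gene_id	gene_symbol	fold_change
1300	COL10A1	42.74
3007	HIST1H1D	29.72
8366	HIST1H4B	25.58
6286	S100P	25.19
1301	COL11A1	24.72
3627	CXCL10	17.83
4283	CXCL9	15.88
1387	CREBBP	12.83
27299	ADAMDEC1	12.78
54986	ULK4	12.46
55771	PRR11	12.02
54790	TET2	11.25
6241	RRM2	10.60
3433	IFIT2	10.49
6999	TDO2	9.73
1656	DDX6	9.72
55088	C10orf118	9.37
9648	GCC2	9.24
6696	SPP1	8.92
2803	GOLGA4	8.57
83540	NUF2	7.73
10112	KIF20A	7.66
9833	MELK	7.59
55165	CEP55	7.50
10142	AKAP9	7.44
9447	AIM2	7.42
54443	ANLN	5.79
6710	SPTB	5.71
7272	TTK	5.64
10635	RAD51AP1	5.49
4069	LYZ	5.37
55183	RIF1	5.34
891	CCNB1	5.34
91543	RSAD2	5.31
81610	FAM83D	5.24
64581	CLEC7A	5.10
10051	SMC4	5.02
4085	MAD2L1	4.96
55872	PBK	4.83
991	CDC20	4.82
9221	NOLC1	4.74
2124	EVI2B	4.66
375248	ANKRD36	4.66
1164	CKS2	4.64
1230	CCR1	4.62
890	CCNA2	4.56
127933	UHMK1	4.49
10274	STAG1	4.45
597	BCL2A1	4.43
55355	HJURP	4.41
54210	TREM1	4.36
253558	LCLAT1	4.26
2706	GJB2	7.33
6498	SKIL	7.13
219285	SAMD9L	7.06
10261	IGSF6	7.01
2335	FN1	6.95
699	BUB1	6.75
1058	CENPA	6.75
332	BIRC5	6.73
51203	NUSAP1	6.59
259266	ASPM	6.54
1063	CENPF	6.49
165918	RNF168	6.44
9232	PTTG1	6.34
5996	RGS1	6.07
29089	UBE2T	5.96
22974	TPX2	5.94
4321	MMP12	5.91
983	CDK1	5.89
85444	LRRCC1	5.87
29121	CLEC2D	3.83
4090	SMAD5	3.80
2123	EVI2A	3.80
57695	USP37	3.79
133418	EMB	3.76
4131	MAP1B	3.76
9787	DLGAP5	3.75
9768	KIAA0101	3.74
54625	PARP14	3.73
2215	FCGR3B	3.71
9134	CCNE2	3.70
3117	HLA-DQA1	3.68
10380	BPNT1	3.67
79056	PRRG4	3.63
10673	TNFSF13B	3.63
8467	SMARCA5	3.61
115908	CTHRC1	3.61
3428	IFI16	3.61
1520	CTSS	3.61
10797	MTHFD2	3.57
55681	SCYL2	3.57
9749	PHACTR2	3.57
94240	EPSTI1	3.56
64151	NCAPG	3.51
25879	DCAF13	3.51
1033	CDKN3	4.24
79801	SHCBP1	4.23
126731	C1orf96	4.21
6772	STAT1	4.20
55729	ATF7IP	4.14
6713	SQLE	4.14
157570	ESCO2	4.10
79871	RPAP2	4.09
9493	KIF23	4.09
4751	NEK2	4.05
10631	POSTN	4.03
23515	MORC3	4.02
7153	TOP2A	4.02
10403	NDC80	4.00
10915	TCERG1	3.99
57650	KIAA1524	3.99
23049	SMG1	3.93
80231	CXorf21	3.87
5111	PCNA	3.86
79682	MLF1IP	3.11
29123	ANKRD11	3.09
5429	POLH	3.09
701	BUB1B	3.07
200030	NBPF11	3.06
55677	IWS1	3.06
160418	TMTC3	3.04
9147	NEMF	3.04
11320	MGAT4A	3.04
5238	PGM3	3.03
2820	GPD2	3.02
388886	FAM211B	3.01
7852	CXCR4	3.00
57082	CASC5	2.99
22926	ATF6	2.98
7594	ZNF43	2.98
968	CD68	2.97
7171	TPM4	2.96
11004	KIF2C	2.96
10808	HSPH1	2.95
84909	C9orf3	2.94
1894	ECT2	2.93
1629	DBT	2.92
116969	ART5	2.90
3227	HOXC11	2.88
116064	LRRC58	3.47
29899	GPSM2	3.47
135114	HINT3	3.45
27333	GOLIM4	3.43
55839	CENPN	3.43
23213	SULF1	3.41
81671	VMP1	3.39
9889	ZBED4	3.36
3092	HIP1	3.34
51512	GTSE1	3.34
92797	HELB	3.34
51426	POLK	3.30
5611	DNAJC3	3.30
6596	HLTF	3.28
9910	RABGAP1L	3.25
528	ATP6V1C1	3.23
3833	KIFC1	3.23
197131	UBR1	3.20
29923	HILPDA	3.20
28998	MRPL13	3.19
58527	C6orf115	3.19
79000	C1orf135	3.19
9857	CEP350	3.18
84296	GINS4	3.18
81034	SLC25A32	3.15
55723	ASF1B	3.14
7110	TMF1	3.14
84081	NSRP1	3.14
23075	SWAP70	3.12
6726	SRP9	2.69
55215	FANCI	2.68
57590	WDFY1	2.67
55142	HAUS2	2.66
23047	PDS5B	2.66
5373	PMM2	2.66
11065	UBE2C	2.66
23085	ERC1	2.66
389197	C4orf50	2.65
11260	XPOT	2.65
29980	DONSON	2.65
64399	HHIP	2.64
6453	ITSN1	2.63
29108	PYCARD	2.63
9877	ZC3H11A	2.62
3149	HMGB3	2.87
10437	IFI30	2.87
57489	ODF2L	2.87
2151	F2RL2	2.86
23215	PRRC2C	2.85
128710	C20orf94	2.85
23594	ORC6	2.84
5205	ATP8B1	2.83
51430	C1orf9	2.80
57405	SPC25	2.80
112401	BIRC8	2.80
3606	IL18	2.80
115362	GBP5	2.80
50515	CHST11	2.79
83461	CDCA3	2.79
10744	PTTG2	2.78
51765	MST4	2.77
10926	DBF4	2.76
27125	AFF4	2.75
10615	SPAG5	2.75
55143	CDCA8	2.74
51602	NOP58	2.74
51478	HSD17B7	2.73
2209	FCGR1A	2.73
9958	USP15	2.72
5469	MED1	2.72
8813	DPM1	2.70
6731	SRP72	2.70
9991	PTBP3	2.70
79866	BORA	2.41
7072	TIA1	2.40
55632	G2E3	2.40
2213	FCGR2B	2.40
3987	LIMS1	2.39
829	CAPZA1	2.39
26973	CHORDC1	2.38
435	ASL	2.38
29979	UBQLN1	2.38
8548	BLZF1	2.37
9694	TTC35	2.37
55055	ZWILCH	2.36
4481	MSR1	2.36
10213	PSMD14	2.35
9966	TNFSF15	2.35
81624	DIAPH3	2.62
79723	SUV39H2	2.61
55789	DEPDC1B	2.61
10097	ACTR2	2.59
23036	ZNF292	2.58
22936	ELL2	2.57
8477	GPR65	2.57
23397	NCAPH	2.57
3015	H2AFZ	2.54
55749	CCAR1	2.53
25937	WWTR1	2.52
360023	ZBTB41	2.51
5080	PAX6	2.51
4193	MDM2	2.51
24137	KIF4A	2.51
9212	AURKB	2.51
168850	ZNF800	2.50
55109	AGGF1	2.49
23185	LARP4B	2.49
51571	FAM49B	2.49
51077	FCF1	2.49
23167	EFR3A	2.49
23468	CBX5	2.48
5396	PRRX1	2.48
10096	ACTR3	2.47
10308	ZNF267	2.47
6782	HSPA13	2.47
3832	KIF11	2.47
917	CD3G	2.47
80821	DDHD1	2.46
52	ACP1	2.46
4179	CD46	2.46
10499	NCOA2	2.44
60558	GUF1	2.44
55676	SLC30A6	2.43
6646	SOAT1	2.43
5440	POLR2K	2.43
84955	NUDCD1	2.42
54739	XAF1	2.42
84295	PHF6	2.23
7295	TXN	2.23
2710	GK	2.23
10905	MAN1A2	2.22
6780	STAU1	2.22
51582	AZIN1	2.35
54843	SYTL2	2.34
9039	UBA3	2.33
933	CD22	2.33
5685	PSMA4	2.33
9885	OSBPL2	2.33
9262	STK17B	2.33
56942	C16orf61	2.32
10767	HBS1L	2.32
87178	PNPT1	2.32
6303	SAT1	2.32
7316	UBC	2.32
4205	MEF2A	2.32
85465	EPT1	2.31
84640	USP38	2.31
5810	RAD1	2.30
64397	ZFP106	2.29
5706	PSMC6	2.29
22948	CCT5	2.29
10672	GNA13	2.29
339344	MYPOP	2.28
7292	TNFSF4	2.28
57103	C12orf5	2.28
388403	YPEL2	2.28
54876	DCAF16	2.27
113235	SLC46A1	2.27
11177	BAZ1A	2.27
339175	METTL2A	2.26
26586	CKAP2	2.26
55785	FGD6	2.26
24145	PANX1	2.25
253461	ZBTB38	2.25
23232	TBC1D12	2.25
995	CDC25C	2.25
55974	SLC50A1	2.25
472	ATM	2.25
23008	KLHDC10	2.24
10024	TROAP	2.24
9521	EEF1E1	2.24
7402	UTRN	2.09
55589	BMP2K	2.08
158747	MOSPD2	2.08
56886	UGGT1	2.07
203100	HTRA4	2.07
10282	BET1	2.22
134430	WDR36	2.21
4299	AFF1	2.21
6747	SSR3	2.21
7334	UBE2N	2.21
5965	RECQL	2.21
4605	MYBL2	2.2
6093	ROCK1	2.19
161725	OTUD7A	2.19
23518	R3HDM1	2.18
2239	GPC4	2.18
28977	MRPL42	2.18
64859	OBFC2A	2.18
3845	KRAS	2.18
51388	NIP7	2.18
7586	ZKSCAN1	2.18
10762	NUP50	2.17
7328	UBE2H	2.17
10730	YME1L1	2.17
23093	TTLL5	2.17
6790	AURKA	2.17
22889	KIAA0907	2.17
10875	FGL2	2.17
23161	SNX13	2.17
9169	SCAF11	2.16
1788	DNMT3A	2.15
9088	PKMYT1	2.15
23033	DOPEY1	2.13
89882	TPD52L3	2.13
6556	SLC11A1	2.13
64216	TFB2M	2.13
3071	NCKAP1L	2.13
51068	NMD3	2.13
509	ATP5C1	2.13
953	ENTPD1	2.13
51105	PHF20L1	2.13
5062	PAK2	2.13
9205	ZMYM5	2.12
55157	DARS2	2.12
8520	HAT1	2.11
79739	TTLL7	2.11
9495	AKAP5	2.10
3181	HNRNPA2B1	2.10
55279	ZNF654	2.07
54499	TMCO1	2.07
81930	KIF18A	2.07
142686	ASB14	2.06
55209	SETD5	2.06
9736	USP34	2.04
116285	ACSM1	2.04
2201	FBN2	2.04
963	CD53	2.04
55159	RFWD3	2.03
9871	SEC24D	2.03
9887	SMG7	2.02
23376	UFL1	2.02
79646	PANK3	2.01
50613	UBQLN3	2.00
201595	STT3B	2.00
59345	GNB4	1.99
5876	RABGGTB	1.99
79820	CATSPERB	1.99
6637	SNRPG	1.99
51330	TNFRSF12A	1.99
9928	KIF14	1.99
286097	EFHA2	1.98
9131	AIFM1	1.98
488	ATP2A2	1.98
23042	PDXDC1	1.98
7114	TMSB4X	1.98
9123	SLC16A3	1.98
54454	ATAD2B	1.97
23143	LRCH1	1.97
4212	MEIS2	1.97
1457	CSNK2A1	1.97
80012	PHC3	1.97
128497	SPATA25	1.96
186	AGTR2	1.96
53981	CPSF2	1.96
56996	SLC12A9	1.96
1584	CYP11B1	1.96
133619	PRRC1	1.96
4288	MKI67	1.96
9014	TAF1B	1.96
55858	TMEM165	1.96
2212	FCGR2A	1.96
389898	UBE2NL	2.10
29850	TRPM5	2.10
3070	HELLS	2.10
331	XIAP	2.09
55751	TMEM184C	2.09
2146	EZH2	2.09
26057	ANKRD17	1.95
128061	C1orf131	1.95
64090	GAL3ST2	1.94
130507	UBR3	1.93
2298	FOXD4	1.93
123169	LEO1	1.93
57187	THOC2	1.93
148789	B3GALNT2	1.93
58508	MLL3	1.92
5701	PSMC2	1.92
148066	ZNRF4	1.92
6670	SP3	1.92
10075	HUWE1	1.96
220988	HNRNPA3	1.96
80146	UXS1	1.95
122011	CSNK1A1L	1.95
150468	CKAP2L	1.95
84624	FNDC1	1.95
7332	UBE2L3	1.92
3336	HSPE1	1.92
54800	KLHL24	1.92
2290	FOXG1	1.91
50848	F11R	1.91
10627	MYL12A	1.91
5074	PAWR	1.91
6476	SI	1.91
1009	CDH11	1.90
29066	ZC3H7A	1.90
51319	RSRC1	1.90
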