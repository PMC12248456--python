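factor_id	level_label	transition	measure	estimate	ci_low	ci_high	case_exposed	case_unexposed	control_exposed	control_unexposed	control_prevalence	source
betel	1-10 pieces per day	N->L	rate_ratio	2.55	1.91	3.41						Table1
betel	11-20 pieces per day	N->L	rate_ratio	5.99	4.25	8.45						Table1
betel	20+ pieces per day	N->L	rate_ratio	10.21	7.53	13.84						Table1
smoking	1-10 sticks per day	N->L	rate_ratio	2.08	1.26	3.42						Table1
smoking	11-20 sticks per day	N->L	rate_ratio	2.83	1.74	4.59						Table1
smoking	20+ sticks per day	N->L	rate_ratio	3.59	2.16	5.95						Table1
betel	1-10 pieces per day	L->E	rate_ratio	1.67	0.84	3.33						Table1
betel	11-20 pieces per day	L->E	rate_ratio	3.35	1.65	6.83						Table1
betel	20+ pieces per day	L->E	rate_ratio	3.52	1.80	6.86						Table1
smoking	1-10 sticks per day	L->E	rate_ratio	1.00	0.42	2.39						Table1
smoking	11-20 sticks per day	L->E	rate_ratio	1.22	0.53	2.83						Table1
smoking	20+ sticks per day	L->E	rate_ratio	1.22	0.51	2.93						Table1
hpv	Positive	N->L	odds_ratio	3.87	2.87	5.21	355	601	89	586	0.13	Table2
miR_3614	aberrant	N->L	odds_ratio	1.78	1.21	2.61						Table2
miR_10b	aberrant	N->L	odds_ratio	1.83	1.19	2.81						Table2
miR_215	aberrant	N->L	odds_ratio	2.73	1.19	2.24						Table2
miR_182	aberrant	N->L	odds_ratio	1.51	1.02	2.24						Table2
PAI1	4G/4G	E->C	odds_ratio	5.00	1.32	8.92	45	59	31	75	0.292	Table3
ACE	I/I	E->C	odds_ratio	9.16	1.14	73.50	30	130	9	144	0.059	Table3
TIMP2	G/G	E->C	odds_ratio	26.33	12.39	55.95	92	66	9	159	0.054	Table3
hOGG1	CC	E->C	odds_ratio	1.42	1.08	1.89	138	482	104	516	0.168	Table3
ERCC5	CT/TT	E->C	odds_ratio	1.42	1.02	1.99	141	98	169	167	0.503	Table3
miR137_meth	Methylated	E->C	odds_ratio	4.80	1.23	18.82	21	78	3	96	0.030	Table3
TIMP3	CT/TT	E->C	odds_ratio	1.52	1.24	1.86	555	192	786	414	0.655	Table3
BRCA1	CT/TT	E->C	odds_ratio	1.61	1.25	2.07	210	237	206	374	0.355	Table3
COL9A1	CT/TT	E->C	odds_ratio	1.64	1.28	2.11	260	187	266	314	0.459	Table3
NOTCH1	AG/AA	E->C	odds_ratio	3.21	1.87	5.51	46	401	20	560	0.034	Table3
HSPA13	GT/TT	E->C	odds_ratio	2.25	1.47	3.45	61	386	38	542	0.066	Table3
NFKB1_rs28362491	Del/Del	E->C	odds_ratio	1.58	1.10	2.26	100	321	90	393	0.186	Table3
NFKB1_rs72696119	GG	E->C	odds_ratio	1.62	1.14	2.32	103	318	91	388	0.190	Table3
H19_rs217727	TT	E->C	odds_ratio	1.70	1.16	2.49	51	380	73	911	0.074	Table3
H19_rs2839701	GG	E->C	odds_ratio	1.53	1.05	2.24	51	393	75	909	0.076	Table3
FAT1	GG	E->C	odds_ratio	1.47	1.03	2.09	75	285	74	412	0.152	Table3
MALAT1	CT/TT	E->C	odds_ratio	0.78	0.63	0.96	402	948	392	807	0.327	Table3
RYR2	GG	E->C	odds_ratio	1.93	1.10	3.39	53	509	17	315	0.051	Table3
P53	Positive	E->C	odds_ratio	1.88	1.39	2.56	279	330	189	421	0.310	Table3
miR_10b	aberrant	E->C	odds_ratio	3.91	2.02	7.57						Table4
miR_3614	aberrant	E->C	odds_ratio	6.09	1.76	21.04						Table4
miR_431	aberrant	E->C	odds_ratio	0.40	0.21	0.76						Table4
miR_486	aberrant	E->C	odds_ratio	0.69	0.47	1.02						Table4
miR_182	aberrant	E->C	odds_ratio	1.70	0.69	4.20						Table4
miR_215	aberrant	E->C	odds_ratio	2.20	0.56	8.66						Table4
miR_7	aberrant	E->C	odds_ratio	1.64	0.69	3.90						Table4
miR_4707	aberrant	E->C	odds_ratio	0.79	0.39	1.57						Table4
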