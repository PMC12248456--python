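transition	factor_id	level_label	coefficient
N->L	betel	1-10 pieces per day	0.9361
N->L	betel	11-20 pieces per day	1.7901
N->L	betel	20+ pieces per day	2.3234
N->L	smoking	1-10 sticks per day	0.7324
N->L	smoking	11-20 sticks per day	1.0428
N->L	smoking	20+ sticks per day	1.2782
N->L	hpv	Positive	1.35
N->L	miR_3614	aberrant	0.5766
N->L	miR_10b	aberrant	0.6043
N->L	miR_215	aberrant	1.0043
N->L	miR_182	aberrant	0.4121
L->E	betel	1-10 pieces per day	0.5128
L->E	betel	11-20 pieces per day	1.2092
L->E	betel	20+ pieces per day	1.2585
L->E	smoking	1-10 sticks per day	0.0
L->E	smoking	11-20 sticks per day	0.2469
L->E	smoking	20+ sticks per day	0.2469
E->C	PAI1	4G/4G	1.61
E->C	ACE	I/I	2.22
E->C	TIMP2	G/G	3.27
E->C	hOGG1	CC	0.3506
E->C	ERCC5	CT/TT	0.3507
E->C	miR137_meth	Methylated	1.5686
E->C	TIMP3	CT/TT	0.4187
E->C	COL9A1	CT/TT	0.4947
E->C	BRCA1	CT/TT	0.4750
E->C	NOTCH1	AG/AA	1.1663
E->C	HSPA13	GT/TT	0.8109
E->C	NFKB1_rs28362491	Del/Del	0.4574
E->C	NFKB1_rs72696119	GG	0.4824
E->C	H19_rs217727	TT	0.5306
E->C	H19_rs2839701	GG	0.4252
E->C	FAT1	GG	0.3853
E->C	MALAT1	CT/TT	-0.7885
E->C	RYR2	GG	0.4947
E->C	P53	Positive	0.6312
E->C	miR_10b	aberrant	1.3635
E->C	miR_3614	aberrant	1.8066
E->C	miR_431	aberrant	-0.9663
E->C	miR_486	aberrant	-0.3711
E->C	miR_182	aberrant	0.5306
E->C	miR_215	aberrant	0.7885
E->C	miR_7	aberrant	0.4947
E->C	miR_4707	aberrant	-0.2357
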