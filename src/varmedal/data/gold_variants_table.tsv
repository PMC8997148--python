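chrom	pos	ref	alt	ref_depth	alt_depth	gene	reported_la	type	aa_change	patient	pli	af_lat	prot_size
11	108175579	G	A	21	19	ATM		Splice	E1892_E37	H4	0	1e-4	3056
15	91341429	A	AG	15	25	BLM		Frameshift	T1074fs	D8	0	-	1417
17	41258472	C	A	54	35	BRCA1		Splice	R71_E4	G8	0	3e-5	1863
13	32914033	CA	C	18	20	BRCA2		Frameshift	S1848fs	E0	0	3e-5	3418
13	32914122	AC	A	52	30	BRCA2		Frameshift	N1877fs	J2	0	3e-5	3418
13	32930653	C	CA	15	17	BRCA2		Frameshift	S2509fs	B2	0	-	3418
13	32937507	A	G	44	30	BRCA2		Missense	D2723G	G2	0	A:C 0	3418
13	32954260	CG	C	23	17	BRCA2		Frameshift	V3079fs	K5	0	2e-4	3418
22	29091718	TA	T	29	23	CHEK2		Frameshift	L413fs	J6	0	-	543
22	29115401	A	ATGAT	28	16	CHEK2		Frameshift	M222fs	F5	0	1e-4	543
22	19222211	C	T	33	36	CLTCL1	No	Missense	E330K	G5	0	9e-4	1640
2	189868190	T	A	35	26	COL3A1	No	Splice	P869P	J6	1	9e-5	1466
7	101926377	C	T	57	41	CUX1	No	Nonsense	Q678*	G2	1	3e-3	678
16	50818362	T	A	30	39	CYLD	No	Splice	I650_E13	C1	1	3e-5	956
18	50734187	G	A	28	23	DCC	No	Splice	V621_E11	H2	0.99	2e-4	1447
X	41206109	T	C	46	39	DDX3X	No	Splice	G539_E15	K3	1	4e-5	662
X	41206562	T	C	44	41	DDX3X	No	Splice	S590_E16	F3	1	2e-3	662
19	45917294	T	C	21	22	ERCC1		Splice	V235_E7	H0	0	6e-5	297
10	50680422	C	T	16	25	ERCC6	No	Splice	R975_E16	G8	0	C:A 3e-5	1493
11	44228353	G	A	33	34	EXT2	No	Nonsense	W535*	A2	0	1e-4	718
6	35425330	C	T	25	34	FANCE	No	Splice	D286_E3	A0	0	3e-4	536
4	187530955	C	G	34	21	FAT1	No	Splice	T3356T	B0	0	0	4588
17	17117000	CG	C	45	40	FLCN	No	Frameshift	R570fs	C0	0.79	C:T 3e-5	579
1	152285000	G	A	46	43	FLG	No	Nonsense	R788*	K8	0	6e-4	4061
1	152285861	G	A	45	34	FLG	No	Nonsense	R501*	K1	0	4e-3	4061
17	42148542	TC	T	11	14	G6PC3	No	Frameshift	I70fs	H0	0	8e-4	346
14	62203827	G	A	20	20	HIF1A	No	Splice	D417_E9	A2	0	2e-4	826
2	48033791	GTTTTTTTTTTTTTTTTTTTTTTTTT	G	15	12	MSH6		Splice	R1334_E9	A0	0	1e-4 &	1360
1	45797228	C	T	25	23	MUTYH		Splice	G396_E13	E7	0	3e-3	546
6	44233331	G	GC	21	12	NFKBIE	No	Frameshift	A57fs	I9	0.77	3e-4	500
5	176722446	TCCCCC	T	27	25	NSD1	No	Frameshift	S2424fs	G7	1	-	2696
16	23641062	CAG	C	25	39	PALB2		Frameshift	S804fs	D6	0	1e-4	1186
16	23641139	G	C	24	36	PALB2		Nonsense	S779*	K6	0	9e-5	1186
3	52620706	TG	T	15	12	PBRM1	No	Splice	E1017_E21	C9	1	0 &	1689
2	190728500	C	T	26	29	PMS1	No	Nonsense	R630*	C9	0	1e-4	932
3	121168273	T	C	19	22	POLQ		Splice	I2385V	B2	0	-	2590
3	121207489	A	T	20	15	POLQ		Nonsense	L1430*	E6	0	9e-5	2590
5	23527845	CA	C	31	42	PRDM9	No	Frameshift	T883fs	B6	0	6e-5	894
1	45294985	C	T	14	13	PTCH2	No	Splice	L406_E10	B1	0	3e-5	1203
17	56774167	C	CT	47	59	RAD51C		Frameshift	A173fs	A5	0	-	376
1	145507646	G	A	15	27	RBM8A	No	UTR_5	E1_UTR_5	G1	0.57	1e-2	174
1	145507646	G	A	18	24	RBM8A	No	UTR_5	E1_UTR_5	G5	0.57	1e-2	174
2	3623181	G	A	51	58	RPS7	No	Splice		E4	0.95	-	194
1	16262459	G	GCCCCCCCCCCCCCCCCCCCCCCCCCC	27	17	SPEN	No	Frameshift	A3242fs	I0	1	9e-4 &	3664
17	7578406	C	T	22	29	TP53		Missense	R175H	I9	0.53	0	393
16	2124201	C	T	44	31	TSC2	No	Splice	R786C	B0	1	0	1807
17	5074956	T	A	83	62	USP6	No	Nonsense	Y1343*	H3	0	9e-5	1406
8	31014882	A	G	13	13	WRN		Splice	K1274_E33	J8	0	1e-4	1432
16	72991713	C	CCCCCCCCC	20	14	ZFHX3	No	Frameshift	A778fs	H6	1	0	3703
X	70466308	GTGGT	G	28	11	ZMYM3	No	Frameshift	P821fs	L2	1	-	1370
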