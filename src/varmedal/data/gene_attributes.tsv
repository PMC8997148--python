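symbol	is_tumor_suppressor	lof_disease_mechanism	pli	protein_size	truncations_in_final_exon
ATM	1	1	0	3056	0
BLM	1	1	0	1417	0
BRCA1	1	1	0	1863	0
BRCA2	1	1	0	3418	0
CHEK2	1	1	0	543	0
CLTCL1	0	1	0	1640	0
COL3A1	0	1	1	1466	0
CUX1	1	1	1	678	0
CYLD	1	1	1	956	0
DCC	1	1	0.99	1447	0
DDX3X	0	1	1	662	0
ERCC1	0	1	0	297	0
ERCC6	1	1	0	1493	0
EXT2	1	1	0	718	0
FANCE	1	1	0	536	0
FAT1	1	1	0	4588	0
FLCN	1	1	0.79	579	0
FLG	0	1	0	4061	1
G6PC3	0	1	0	346	0
HIF1A	0	1	0	826	0
MSH6	1	1	0	1360	0
MUTYH	1	1	0	546	0
NFKBIE	0	1	0.77	500	0
NSD1	0	1	1	2696	0
PALB2	1	1	0	1186	0
PBRM1	1	1	1	1689	0
PMS1	1	1	0	932	0
POLQ	0	1	0	2590	0
PRDM9	0	1	0	894	0
PTCH2	1	1	0	1203	0
RAD51C	1	1	0	376	0
RBM8A	0	1	0.57	174	0
RPS7	0	1	0.95	194	0
SPEN	0	1	1	3664	0
TP53	1	1	0.53	393	0
TSC2	1	1	1	1807	0
USP6	0	1	0	1406	0
WRN	1	1	0	1432	0
ZFHX3	1	1	1	3703	0
ZMYM3	0	1	1	1370	0
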