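gene_id	meth_delta	expr_log2
ANGPTL2	22.32	-2.20
BIN2	18.44	-3.19
BRDT	12.26	-3.01
CCRL2	23.06	-1.69
CYP2W1	15.00	-3.72
FAM111A	14.58	-1.10
FBXO17	16.93	-1.49
FGL2	26.25	-1.49
GJB5	-24.29	2.51
GREB1	17.90	-1.06
HSPB2	10.37	-1.28
ISLR	18.62	-1.23
LOC100289019	14.03	1.06
LOC401109	-13.71	1.16
MAL	10.43	2.36
PLEKHA6	20.11	1.58
PTPRE	10.36	-1.03
RAB42	18.59	-1.51
RHOBTB2	14.66	-1.38
SEMA6D	24.79	-1.56
SNORD110	13.68	-1.85
SNRPF	14.89	-1.43
ST5	19.15	1.36
STRA6	16.80	1.71
SYNPO	23.10	1.27
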