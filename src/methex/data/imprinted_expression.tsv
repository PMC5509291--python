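gene_id	avg_first	avg_third	log2_printed	imprint_status
SLC22A18	23.25	3.90	-2.58	maternal
PEG10	612.10	188.34	-1.70	paternal
MEST	291.60	93.04	-1.65	paternal
NAP1L5	4.26	1.48	-1.53	paternal
MIMT1	1.34	0.50	-1.42	paternal
PSIMCT-1	3.246	1.35	-1.26	paternal
PEG3	194.33	81.51	-1.25	paternal
LIN28B	23.84	10.08	-1.24	paternal
DGCR6	1.38	0.64	-1.11	unknown
PLAGL1	119.87	56.75	-1.08	paternal
ANO1	3.90	8.07	1.05	maternal
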