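accession	mirna_name	total	l0_count	l1_count
MIMAT0002819	hsa-miR-193b-3p	16	1	15
MIMAT0000250	hsa-miR-139-5p	28	10	18
MIMAT0000437	hsa-miR-145-5p	86	22	64
MIMAT0000423	hsa-miR-125b-5p	211	16	195
MIMAT0000443	hsa-miR-125a-5p	206	14	192
MIMAT0000097	hsa-miR-99a-5p	14	1	13
MIMAT0000265	hsa-miR-204-5p	64	18	46
MIMAT0000076	hsa-miR-21-5p	91	16	75
MIMAT0000064	hsa-let-7c	96	20	76
MIMAT0000421	hsa-miR-122-5p	5	3	2
MIMAT0000098	hsa-miR-100-5p	14	1	13
MIMAT0000272	hsa-miR-215	3	3	0
MIMAT0000271	hsa-miR-214-3p	14	8	6
MIMAT0000738	hsa-miR-383	34	3	31
MIMAT0002856	hsa-miR-520d-3p	146	23	123
MIMAT0000077	hsa-miR-22-3p	46	11	35
MIMAT0002820	hsa-miR-497-5p	267	32	235
MIMAT0000089	hsa-miR-31-5p	34	3	31
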