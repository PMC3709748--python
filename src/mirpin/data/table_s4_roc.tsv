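accession	mirna_name	auc	p_value
MIMAT0002856	hsa-miR-520d-3p	0.49	0.549112
MIMAT0000265	hsa-miR-204-5p	0.98	6.47e-10
MIMAT0000272	hsa-miR-215	0.21	0.999782
MIMAT0000271	hsa-miR-214-3p	0.68	0.010387
MIMAT0002820	hsa-miR-497-5p	0.99	2.75e-10
MIMAT0000076	hsa-miR-21-5p	0.78	0.000184
MIMAT0000738	hsa-miR-383	0.60	0.106284
MIMAT0000423	hsa-miR-125b-5p	0.99	2.48e-10
MIMAT0000064	hsa-let-7c	0.93	3.79e-08
MIMAT0000089	hsa-miR-31-5p	0.80	8.63e-05
MIMAT0000077	hsa-miR-22-3p	0.27	0.99749
MIMAT0000098	hsa-miR-100-5p	0.98	5.55e-10
MIMAT0000097	hsa-miR-99a-5p	0.99	2.55e-10
MIMAT0000443	hsa-miR-125a-5p	0.31	0.990694
MIMAT0002819	hsa-miR-193b-3p	0.41	0.86128
MIMAT0000250	hsa-miR-139-5p	0.99	2.42e-10
MIMAT0000437	hsa-miR-145-5p	0.96	3.14e-09
MIMAT0000421	hsa-miR-122-5p	0.48	0.597483
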