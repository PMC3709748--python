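accession	mirna_name	fold_change
MIMAT0004761	hsa-miR-483-5p	0.01
MIMAT0004552	hsa-miR-139-3p	0.01
MIMAT0000738	hsa-miR-383	0.02
MIMAT0002856	hsa-miR-520d-3p	0.02
MIMAT0002811	hsa-miR-202-3p	0.03
MIMAT0002177	hsa-miR-486-5p	0.04
MIMAT0022721	hsa-miR-1247-3p	0.05
MIMAT0002175	hsa-miR-485-5p	0.06
MIMAT0000265	hsa-miR-204-5p	0.07
MIMAT0000752	hsa-miR-328	0.07
MIMAT0000421	hsa-miR-122-5p	0.07
MIMAT0000447	hsa-miR-134	0.08
MIMAT0000722	hsa-miR-370	0.09
MIMAT0004513	hsa-miR-101-5p	0.09
MIMAT0000446	hsa-miR-127-3p	0.10
MIMAT0000097	hsa-miR-99a-5p	0.10
MIMAT0004566	hsa-miR-218-2-3p	0.10
MIMAT0000729	hsa-miR-376a-3p	0.11
MIMAT0009197	hsa-miR-205-3p	0.11
MIMAT0004615	hsa-miR-195-3p	0.11
MIMAT0005899	hsa-miR-1247-5p	0.11
MIMAT0000720	hsa-miR-376c	0.12
MIMAT0000762	hsa-miR-324-3p	0.12
MIMAT0004679	hsa-miR-296-3p	0.12
MIMAT0004614	hsa-miR-193a-5p	0.12
MIMAT0003880	hsa-miR-671-5p	0.12
MIMAT0004795	hsa-miR-574-5p	0.12
MIMAT0004599	hsa-miR-143-5p	0.13
MIMAT0000423	hsa-miR-125b-5p	0.13
MIMAT0004957	hsa-miR-760	0.13
MIMAT0004911	hsa-miR-874	0.14
MIMAT0004603	hsa-miR-125b-2-3p	0.15
MIMAT0004952	hsa-miR-665	0.15
MIMAT0018205	hsa-miR-3928	0.15
MIMAT0004767	hsa-miR-193b-5p	0.15
MIMAT0002861	hsa-miR-518e-3p	0.15
MIMAT0004604	hsa-miR-127-5p	0.16
MIMAT0002807	hsa-miR-491-5p	0.16
MIMAT0004689	hsa-miR-377-5p	0.16
MIMAT0004762	hsa-miR-486-3p	0.16
MIMAT0000732	hsa-miR-378a-3p	0.17
MIMAT0017981	hsa-miR-3605-5p	0.18
MIMAT0004605	hsa-miR-129-2-3p	0.19
MIMAT0006789	hsa-miR-1468	0.20
MIMAT0000737	hsa-miR-382-5p	0.21
MIMAT0000077	hsa-miR-22-3p	0.21
MIMAT0000089	hsa-miR-31-5p	0.21
MIMAT0004612	hsa-miR-186-3p	0.21
MIMAT0004592	hsa-miR-125b-1-3p	0.22
MIMAT0001639	hsa-miR-409-3p	0.22
MIMAT0015032	hsa-miR-3158-3p	0.22
MIMAT0004496	hsa-miR-23a-5p	0.22
MIMAT0000690	hsa-miR-296-5p	0.22
MIMAT0000731	hsa-miR-378a-5p	0.23
MIMAT0000448	hsa-miR-136-5p	0.23
MIMAT0004796	hsa-miR-576-3p	0.23
MIMAT0010133	hsa-miR-2110	0.23
MIMAT0004951	hsa-miR-887	0.23
MIMAT0003239	hsa-miR-574-3p	0.25
MIMAT0005901	hsa-miR-1249	0.25
MIMAT0000510	hsa-miR-320a	0.26
MIMAT0002172	hsa-miR-376b	0.26
MIMAT0000250	hsa-miR-139-5p	0.27
MIMAT0005825	hsa-miR-1180	0.27
MIMAT0000437	hsa-miR-145-5p	0.28
MIMAT0004601	hsa-miR-145-3p	0.28
MIMAT0003322	hsa-miR-652-3p	0.28
MIMAT0000756	hsa-miR-326	0.28
MIMAT0000098	hsa-miR-100-5p	0.29
MIMAT0003296	hsa-miR-627	0.29
MIMAT0002820	hsa-miR-497-5p	0.31
MIMAT0004507	hsa-miR-92a-1-5p	0.31
MIMAT0000271	hsa-miR-214-3p	0.32
MIMAT0004702	hsa-miR-339-3p	0.33
MIMAT0004611	hsa-miR-185-3p	0.33
MIMAT0000064	hsa-let-7c	0.34
MIMAT0004673	hsa-miR-29c-5p	0.35
MIMAT0000733	hsa-miR-379-5p	0.35
MIMAT0004594	hsa-miR-132-5p	0.35
MIMAT0000765	hsa-miR-335-5p	0.35
MIMAT0002819	hsa-miR-193b-3p	0.36
MIMAT0000088	hsa-miR-30a-3p	0.36
MIMAT0005951	hsa-miR-1307-3p	0.36
MIMAT0004597	hsa-miR-140-3p	0.37
MIMAT0004556	hsa-miR-10b-3p	0.37
MIMAT0000272	hsa-miR-215	0.37
MIMAT0004511	hsa-miR-99a-3p	0.37
MIMAT0000443	hsa-miR-125a-5p	0.38
MIMAT0004482	hsa-let-7b-3p	0.38
MIMAT0000076	hsa-miR-21-5p	6.58
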