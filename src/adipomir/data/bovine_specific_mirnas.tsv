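mirna	chromosome	clustered	location	host_gene	expression_mean	expression_sd	predicted_targets	seed
bta-miR-2478	chr9	no	intergenic	-	10.90	0.63	116	UAUCCCA
bta-miR-126-3p	chr11	no	intronic	EGFL7	7.71	0.63	26	GUACCGU
bta-miR-2305	chr13	no	intronic	RIN2	6.09	1.19	109	GGGGGUG
bta-miR-2328-3p	chr18	no	intronic	ZNF821	5.39	1.22	144	CCCCCUC
bta-miR-1584	chr3	no	intronic	TAGLN2	5.13	0.85	135	UGGGGCU
bta-miR-2888	chr21	no	intergenic	-	4.60	0.98	93	GUGGGGU
bta-miR-199c	chr19	no	intronic	NUP88	4.01	0.38	704	ACAGUAG
bta-miR-2881	chr7	no	intergenic	-	3.95	0.88	59	GGGCGGG
bta-miR-2332	chr19	no	intronic	UTP6	3.39	0.39	392	GGUUUAA
bta-miR-2412	chr3	no	intergenic	-	3.34	0.99	135	UGGGGCU
bta-miR-2455	chr7	no	intergenic	-	3.07	1.14	413	CUGUGCU
bta-miR-2316	chr15	no	intergenic	-	2.53	0.76	8	CUCCGGC
bta-miR-2374	chr22	no	intergenic	-	1.98	0.83	135	UGGGGCU
bta-miR-2483	chrX	no	intergenic	-	1.62	1.12	381	AACAUCU
bta-miR-2474	chr8	no	intronic	SHB	1.61	0.96	5	ACCGGGC
bta-miR-425-5p	chr22	yes	intergenic	-	1.61	0.66	74	UGACACG
bta-miR-2892	chr12	no	intergenic	-	1.52	0.65	3	GCGACGG
bta-miR-1434	chr7	no	intronic	EEF2	1.02	0.57	1134	AAGAAAU
bta-miR-2391	chr26	no	intergenic	-	0.55	0.40	2732	AAAAAAA
bta-miR-2898	chr8	no	intergenic	-	0.37	0.50	134	GGUGGAG
bta-miR-2424	chr5	no	intronic	NCAPD2	0.29	0.49	225	GAUCUUU
bta-miR-2885	chr29	no	intergenic	-	0.20	0.34	27	GGCGGCA
bta-miR-2882	chr7	no	exonic	SMARCA4	0.15	0.23	19	GCCCGGG
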