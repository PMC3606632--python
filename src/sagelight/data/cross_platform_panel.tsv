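gene_id	description	log2_ratio_sage	log2_ratio_microarray	log2_ratio_qpcr
CC1G_04976	Thiazole biosynthetic enzyme	6.48	3.34	3.80
CC1G_03790	Glutamate decarboxylase	5.55	1.64	3.55
CC1G_00577	CMGC/MAPK protein kinase	4.41	1.41	2.76
CC1G_03377	Protoporphyrinogen oxidase	3.41	-0.17	1.66
CC1G_00689	Thioredoxin	3.16	0.72	2.91
CC1G_07379	Hypothetical protein	1.57	0.19	1.59
CC1G_06934	Hypothetical protein	1.06	-0.85	1.34
CC1G_02958	Actin cytoskeleton protein VIP1	0.82	0.79	0.92
CC1G_10110	Ubiquitin-carboxy protein fusion	-0.05	-0.35	-0.32
CC1G_03278	ATP synthase subunit 5	-0.07	-0.21	-0.41
CC1G_07540	60S ribosomal protein L34-b	-0.16	-0.64	-0.45
CC1G_07277	40S ribosomal protein S14	-0.95	-0.41	-0.78
CC1G_01940	ATP-synthase delta-subunit	-1.34	-0.73	-1.23
CC1G_03707	Prohibitin	-1.43	-0.37	-1.44
CC1G_09336	Basic leucine zipper & W2 domain-containing protein 2	-1.97	-1.17	-1.98
CC1G_06761	Glycine dehydrogenase	-4.42	0.45	-0.82
CC1G_14100	Hypothetical protein	-5.82	-1.53	-3.42
CC1G_01315	Endochitinase	-6.63	-1.45	-4.66
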