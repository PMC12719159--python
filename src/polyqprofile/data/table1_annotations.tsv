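variant_id	consequence	cadd	effect_allele	eur_af	splice_flag	eqtl_gene_ids
rs719316	intronic	5.92	T	0.529	false	.
rs17603856	intronic	10.94	G	0.346	false	.
rs6459480	intronic	1.82	A	0.509	false	.
rs9297016	intronic	2.57	G	0.576	false	.
rs7772172	intronic	5.02	G	0.576	false	.
rs909788	intronic	5.75	C	0.545	false	.
rs6459472	intronic	2.97	G	0.573	false	.
rs6915310	intronic	4.27	T	0.182	false	.
rs9367926	intronic	6.59	G	0.18	false	.
rs2237199	intronic	3.49	A	0.112	false	.
rs73366713	intronic	2.84	A	0.131	false	.
rs7770062	intronic	2.33	A	0.131	false	.
rs3819405	intronic	12.1	T	0.34	false	.
rs653178	intronic	1.59	T	0.534	false	.
rs848130	intronic	2.02	A	0.192	false	.
rs832190	intronic	0.58	T	0.603	false	.
rs3821902	intronic	0.81	G	0.15	false	.
rs13434089	intronic	4.59	C	0.141	false	.
rs5021328	intronic	0.63	C	0.644	false	.
rs16003	intronic	8.26	T	0.463	false	.
rs363096	splice	6.29	C	0.591	true	.
rs7685686	intronic	6.39	G	0.433	false	.
rs82334	intronic	4.13	C	0.323	false	.
rs61348208	intronic	5.46	T	0.389	false	.
rs2071703	intronic	2.52	C	0.325	false	.
rs113928896	intronic	0.32	T	0.143	false	.
rs362307	UTR	3.23	T	0.063	false	.
rs6828882	intronic	8.54	G	0.101	false	.
rs2798297	intronic	2.08	A	0.353	false	.
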