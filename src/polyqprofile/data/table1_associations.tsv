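gene_symbol	gene_id	trait_label	trait_category	study_id	pubmed_id	source	l2g	variant_id	chrom	pos	gwas_p	effect	effect_ci_low	effect_ci_high	effect_type	ancestries
ATXN1	ENSG00000124788	multiple sclerosis	disease	STUDY_bib35	30000035	GWAS_catalog	0.79	rs719316	6	16310000	2e-13	1.07	1.05	1.09	odds_ratio	EUR
ATXN1	ENSG00000124788	systemic lupus erythematosus	disease	STUDY_bib36	30000036	GWAS_catalog	0.79	rs17603856	6	16320000	3e-12	0.88	0.85	0.91	odds_ratio	EUR
ATXN1	ENSG00000124788	cognitive ability, years of educational attainment or schizophrenia	measurement	STUDY_bib37	30000037	GWAS_catalog	0.69	rs6459480	6	16330100	2e-10	.	.	.	NA	EUR
ATXN1	ENSG00000124788	household income	measurement	STUDY_bib38	30000038	GWAS_catalog	0.7	rs6459480	6	16330100	5e-10	-0.01	-0.02	0.01	beta	EUR
ATXN1	ENSG00000124788	educational attainment	measurement	STUDY_bib39	30000039	GWAS_catalog	0.68	rs9297016	6	16330200	1e-09	-0.01	-0.01	0.006	beta	EUR
ATXN1	ENSG00000124788	educational attainment: years of education	measurement	STUDY_bib40	30000040	GWAS_catalog	0.68	rs7772172	6	16330300	1e-08	-0.01	-0.02	0.01	beta	EUR
ATXN1	ENSG00000124788	educational attainment (years of education)	measurement	STUDY_bib39	30000039	GWAS_catalog	0.77	rs909788	6	16330000	4e-08	-0.01	-0.011	0.005	beta	EUR
ATXN1	ENSG00000124788	central corneal thickness	measurement	STUDY_bib41	30000041	GWAS_catalog	0.72	rs6459472	6	16340000	3e-09	.	.	.	NA	EUR
ATXN1	ENSG00000124788	male-pattern baldness	measurement	STUDY_bib42	30000042	GWAS_catalog	0.72	rs6915310	6	16350100	5e-20	0.04	0.03	0.05	beta	EUR
ATXN1	ENSG00000124788	balding type 1	measurement	STUDY_bib43	30000043	GWAS_catalog	0.71	rs9367926	6	16350000	6e-12	.	.	.	NA	EUR
ATXN1	ENSG00000124788	subcutaneous adipose tissue attenuation	measurement	STUDY_bib44	30000044	GWAS_catalog	0.57	rs2237199	6	16360000	1e-08	5.67	3.73	7.61	beta	EUR
ATXN1	ENSG00000124788	atrial fibrillation	disease	STUDY_bib45	30000045	GWAS_catalog	0.55	rs73366713	6	16370100	1.53e-25	0.9	0.88	0.92	odds_ratio	EUR
ATXN1	ENSG00000124788	atrial fibrillation	disease	STUDY_bib46	30000046	GWAS_catalog	0.54	rs7770062	6	16370000	9e-21	0.9	0.88	0.92	odds_ratio	EUR
ATXN1	ENSG00000124788	breast cancer	disease	STUDY_bib47	30000047	GWAS_catalog	0.53	rs3819405	6	16380000	1.65e-08	0.96	0.95	0.97	odds_ratio	EUR
ATXN2	ENSG00000204842	celiac disease	disease	STUDY_bib48	30000048	GWAS_catalog	0.51	rs653178	12	111410000	6e-14	0.83	0.78	0.87	odds_ratio	EUR
ATXN2	ENSG00000204842	type 1 diabetes	disease	STUDY_bib49	30000049	GWAS_catalog	0.67	rs848130	12	111420000	1.6e-14	0.85	0.82	0.89	odds_ratio	EUR
ATXN7	ENSG00000163635	schizophrenia	disease	STUDY_bib50	30000050	GWAS_catalog	0.51	rs832190	3	63810000	4e-08	.	.	.	NA	EUR
ATXN7	ENSG00000163635	breast cancer	disease	STUDY_bib47	30000047	GWAS_catalog	0.54	rs3821902	3	63820000	2.99e-12	1.06	1.05	1.08	odds_ratio	EUR
ATXN7	ENSG00000163635	type 2 diabetes	disease	STUDY_bib51	30000051	GWAS_catalog	0.55	rs13434089	3	63830000	4e-31	-0.06	-0.07	0.05	beta	EUR
CACNA1A	ENSG00000141837	appendicular lean mass	measurement	STUDY_bib52	30000052	GWAS_catalog	0.86	rs5021328	19	13210000	6.6e-09	-0.01	-0.02	0.01	beta	EUR
CACNA1A	ENSG00000141837	positive affect	measurement	STUDY_bib53	30000053	GWAS_catalog	0.84	rs16003	19	13220000	3e-08	0.01	0.0	0.01	beta	EUR
CACNA1A	ENSG00000141837	depressive symptoms	measurement	STUDY_bib53	30000053	GWAS_catalog	0.84	rs16003	19	13220000	3e-08	0.01	0.0	0.01	beta	EUR
HTT	ENSG00000197386	noncognitive aspects of educational attainment	measurement	STUDY_bib54	30000054	GWAS_catalog	0.72	rs363096	4	3080000	1e-12	0.05	0.04	0.06	beta	EUR
HTT	ENSG00000197386	educational attainment: years of education	measurement	STUDY_bib43	30000043	GWAS_catalog	0.74	rs363096	4	3080000	1e-10	.	.	.	NA	EUR
HTT	ENSG00000197386	depression	disease	STUDY_bib55	30000055	GWAS_catalog	0.59	rs7685686	4	3090100	6e-15	0.983	0.979	0.987	odds_ratio	EUR
HTT	ENSG00000197386	frailty index	measurement	STUDY_bib56	30000056	GWAS_catalog	0.54	rs82334	4	3090200	3.1e-10	-0.02	-0.03	0.02	beta	EUR
HTT	ENSG00000197386	parental lifespan	measurement	STUDY_bib57	30000057	GWAS_catalog	0.63	rs61348208	4	3090000	6e-09	0.23	0.15	0.31	beta	EUR
HTT	ENSG00000197386	gastroesophageal reflux disease	disease	STUDY_bib58	30000058	GWAS_catalog	0.54	rs7685686	4	3090100	1.1e-08	0.97	0.96	0.98	odds_ratio	EUR
HTT	ENSG00000197386	aging traits: health span, parental lifespan or longevity	measurement	STUDY_bib59	30000059	GWAS_catalog	0.62	rs61348208	4	3090000	3e-08	.	.	.	NA	EUR
HTT	ENSG00000197386	vertex-wise sulcal depth	measurement	STUDY_bib60	30000060	GWAS_catalog	0.6	rs2071703	4	3090300	3e-08	5.57	3.6	7.54	beta	EUR
HTT	ENSG00000197386	highest math class taken	measurement	STUDY_bib39	30000039	GWAS_catalog	0.55	rs113928896	4	3100000	2e-09	0.02	0.01	0.02	beta	EUR
HTT	ENSG00000197386	automobile speeding propensity	measurement	STUDY_bib61	30000061	GWAS_catalog	0.51	rs362307	4	3110000	6e-14	-0.03	-0.04	0.02	beta	EUR
HTT	ENSG00000197386	worry/vulnerability: special factor of neuroticism	measurement	STUDY_bib62	30000062	GWAS_catalog	0.54	rs362307	4	3110000	1e-09	0.01	0.005	0.011	beta	EUR
HTT	ENSG00000197386	walking pace	measurement	STUDY_bib63	30000063	GWAS_catalog	0.54	rs362307	4	3110000	1e-09	-0.01	-0.02	0.01	beta	EUR
HTT	ENSG00000197386	type 2 diabetes	disease	STUDY_bib64	30000064	GWAS_catalog	0.54	rs362307	4	3110000	1e-09	1.08	1.05	1.11	odds_ratio	EUR
HTT	ENSG00000197386	predicted visceral adipose tissue	measurement	STUDY_bib65	30000065	GWAS_catalog	0.54	rs362307	4	3110000	2e-09	0.03	0.02	0.04	beta	EUR
HTT	ENSG00000197386	monobrow	measurement	STUDY_bib66	30000066	GWAS_catalog	0.53	rs6828882	4	3120000	1e-22	.	.	.	NA	EUR
HTT	ENSG00000197386	metabolic biomarkers	measurement	STUDY_bib67	30000067	GWAS_catalog	0.52	rs2798297	4	3130000	1e-24	.	.	.	NA	EUR
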