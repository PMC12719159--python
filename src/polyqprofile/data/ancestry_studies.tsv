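gene_symbol	gene_id	trait_label	trait_category	study_id	pubmed_id	source	l2g	variant_id	chrom	pos	gwas_p	effect	effect_ci_low	effect_ci_high	effect_type	ancestries
ATXN1	ENSG00000124788	ancestry panel trait 01	measurement	ANC_S01	30000001	GWAS_catalog	0.6	rs8200001	6	16000100	1e-09	.	.	.	NA	EUR
ATXN1	ENSG00000124788	ancestry panel trait 02	measurement	ANC_S02	30000002	GWAS_catalog	0.6	rs8200002	6	16000200	1e-09	.	.	.	NA	EUR
ATXN1	ENSG00000124788	ancestry panel trait 03	measurement	ANC_S03	30000003	GWAS_catalog	0.6	rs8200003	6	16000300	1e-09	.	.	.	NA	EUR
ATXN1	ENSG00000124788	ancestry panel trait 04	measurement	ANC_S04	30000004	GWAS_catalog	0.6	rs8200004	6	16000400	1e-09	.	.	.	NA	EUR
ATXN1	ENSG00000124788	ancestry panel trait 05	measurement	ANC_S05	30000005	GWAS_catalog	0.6	rs8200005	6	16000500	1e-09	.	.	.	NA	EUR
ATXN1	ENSG00000124788	ancestry panel trait 06	measurement	ANC_S06	30000006	GWAS_catalog	0.6	rs8200006	6	16000600	1e-09	.	.	.	NA	EUR
ATXN1	ENSG00000124788	ancestry panel trait 07	measurement	ANC_S07	30000007	GWAS_catalog	0.6	rs8200007	6	16000700	1e-09	.	.	.	NA	EUR
ATXN1	ENSG00000124788	ancestry panel trait 08	measurement	ANC_S08	30000008	GWAS_catalog	0.6	rs8200008	6	16000800	1e-09	.	.	.	NA	EUR
ATXN1	ENSG00000124788	ancestry panel trait 09	measurement	ANC_S09	30000009	GWAS_catalog	0.6	rs8200009	6	16000900	1e-09	.	.	.	NA	EUR
ATXN1	ENSG00000124788	ancestry panel trait 10	measurement	ANC_S10	30000010	GWAS_catalog	0.6	rs8200010	6	16001000	1e-09	.	.	.	NA	EUR
ATXN1	ENSG00000124788	ancestry panel trait 11	measurement	ANC_S11	30000011	GWAS_catalog	0.6	rs8200011	6	16001100	1e-09	.	.	.	NA	EUR
ATXN1	ENSG00000124788	ancestry panel trait 12	measurement	ANC_S12	30000012	GWAS_catalog	0.6	rs8200012	6	16001200	1e-09	.	.	.	NA	EUR
ATXN1	ENSG00000124788	ancestry panel trait 13	measurement	ANC_S13	30000013	GWAS_catalog	0.6	rs8200013	6	16001300	1e-09	.	.	.	NA	EUR
ATXN1	ENSG00000124788	ancestry panel trait 14	measurement	ANC_S14	30000014	GWAS_catalog	0.6	rs8200014	6	16001400	1e-09	.	.	.	NA	EUR
ATXN1	ENSG00000124788	ancestry panel trait 15	measurement	ANC_S15	30000015	GWAS_catalog	0.6	rs8200015	6	16001500	1e-09	.	.	.	NA	EUR
ATXN1	ENSG00000124788	ancestry panel trait 16	measurement	ANC_S16	30000016	GWAS_catalog	0.6	rs8200016	6	16001600	1e-09	.	.	.	NA	EUR
ATXN1	ENSG00000124788	ancestry panel trait 17	measurement	ANC_S17	30000017	GWAS_catalog	0.6	rs8200017	6	16001700	1e-09	.	.	.	NA	EUR
ATXN1	ENSG00000124788	ancestry panel trait 18	measurement	ANC_S18	30000018	GWAS_catalog	0.6	rs8200018	6	16001800	1e-09	.	.	.	NA	EUR
ATXN1	ENSG00000124788	ancestry panel trait 19	measurement	ANC_S19	30000019	GWAS_catalog	0.6	rs8200019	6	16001900	1e-09	.	.	.	NA	EUR
ATXN1	ENSG00000124788	ancestry panel trait 20	measurement	ANC_S20	30000020	GWAS_catalog	0.6	rs8200020	6	16002000	1e-09	.	.	.	NA	EUR
ATXN1	ENSG00000124788	ancestry panel trait 21	measurement	ANC_S21	30000021	GWAS_catalog	0.6	rs8200021	6	16002100	1e-09	.	.	.	NA	EUR
ATXN1	ENSG00000124788	ancestry panel trait 22	measurement	ANC_S22	30000022	GWAS_catalog	0.6	rs8200022	6	16002200	1e-09	.	.	.	NA	EUR
ATXN1	ENSG00000124788	ancestry panel trait 23	measurement	ANC_S23	30000023	GWAS_catalog	0.6	rs8200023	6	16002300	1e-09	.	.	.	NA	EUR
ATXN1	ENSG00000124788	ancestry panel trait 24	measurement	ANC_S24	30000024	GWAS_catalog	0.6	rs8200024	6	16002400	1e-09	.	.	.	NA	EUR
ATXN1	ENSG00000124788	ancestry panel trait 25	measurement	ANC_S25	30000025	GWAS_catalog	0.6	rs8200025	6	16002500	1e-09	.	.	.	NA	EUR
ATXN1	ENSG00000124788	ancestry panel trait 26	measurement	ANC_S26	30000026	GWAS_catalog	0.6	rs8200026	6	16002600	1e-09	.	.	.	NA	EUR
ATXN1	ENSG00000124788	ancestry panel trait 27	measurement	ANC_S27	30000027	GWAS_catalog	0.6	rs8200027	6	16002700	1e-09	.	.	.	NA	EUR
ATXN1	ENSG00000124788	ancestry panel trait 28	measurement	ANC_S28	30000028	GWAS_catalog	0.6	rs8200028	6	16002800	1e-09	.	.	.	NA	EUR
ATXN1	ENSG00000124788	ancestry panel trait 29	measurement	ANC_S29	30000029	GWAS_catalog	0.6	rs8200029	6	16002900	1e-09	.	.	.	NA	EUR
ATXN1	ENSG00000124788	ancestry panel trait 30	measurement	ANC_S30	30000030	GWAS_catalog	0.6	rs8200030	6	16003000	1e-09	.	.	.	NA	EUR
ATXN1	ENSG00000124788	ancestry panel trait 31	measurement	ANC_S31	30000031	GWAS_catalog	0.6	rs8200031	6	16003100	1e-09	.	.	.	NA	EUR
ATXN1	ENSG00000124788	ancestry panel trait 32	measurement	ANC_S32	30000032	GWAS_catalog	0.6	rs8200032	6	16003200	1e-09	.	.	.	NA	EAS,EUR
ATXN1	ENSG00000124788	ancestry panel trait 33	measurement	ANC_S33	30000033	GWAS_catalog	0.6	rs8200033	6	16003300	1e-09	.	.	.	NA	EAS,EUR
ATXN1	ENSG00000124788	ancestry panel trait 34	measurement	ANC_S34	30000034	GWAS_catalog	0.6	rs8200034	6	16003400	1e-09	.	.	.	NA	EAS,EUR
ATXN1	ENSG00000124788	ancestry panel trait 35	measurement	ANC_S35	30000035	GWAS_catalog	0.6	rs8200035	6	16003500	1e-09	.	.	.	NA	EAS,EUR
ATXN1	ENSG00000124788	ancestry panel trait 36	measurement	ANC_S36	30000036	GWAS_catalog	0.6	rs8200036	6	16003600	1e-09	.	.	.	NA	AFR,EUR
ATXN1	ENSG00000124788	ancestry panel trait 37	measurement	ANC_S37	30000037	GWAS_catalog	0.6	rs8200037	6	16003700	1e-09	.	.	.	NA	AFR,EAS,EUR
ATXN1	ENSG00000124788	ancestry panel trait 38	measurement	ANC_S38	30000038	GWAS_catalog	0.6	rs8200038	6	16003800	1e-09	.	.	.	NA	AFR,EAS,EUR
ATXN1	ENSG00000124788	ancestry panel trait 39	measurement	ANC_S39	30000039	GWAS_catalog	0.6	rs8200039	6	16003900	1e-09	.	.	.	NA	AFR,EAS,EUR
ATXN1	ENSG00000124788	ancestry panel trait 40	measurement	ANC_S40	30000040	GWAS_catalog	0.6	rs8200040	6	16004000	1e-09	.	.	.	NA	AFR,EAS,EUR
ATXN1	ENSG00000124788	ancestry panel trait 41	measurement	ANC_S41	30000041	GWAS_catalog	0.6	rs8200041	6	16004100	1e-09	.	.	.	NA	EAS
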