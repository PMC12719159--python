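# synthetic fixture: structure transcribed from the published study tables; positions, LD, identifiers and filler trait labels are synthetic
# the fifth constraint-unfavorable gene is shown only graphically in the source; this fixture assigns it to CACNA1A (group mean is invariant)
gene_symbol	pli	oe_lof	tissue_class	druggable_evidence
AR	0.55	0.43	tissue_enhanced	true
ATN1	0.97	0.12	low_tissue_specificity	false
ATXN1	1.0	0.08	low_tissue_specificity	false
ATXN2	0.62	0.46	low_tissue_specificity	true
ATXN3	0.08	0.74	low_tissue_specificity	false
ATXN7	0.99	0.15	low_tissue_specificity	true
CACNA1A	1.0	0.06	tissue_enriched	true
HTT	1.0	0.03	low_tissue_specificity	true
TBP	0.45	0.39	low_tissue_specificity	false
THAP11	0.3	0.58	low_tissue_specificity	false
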