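gene_symbol	phenotype_label	mim_number	inheritance	susceptibility_flag	cag_related_flag
AR	androgen insensitivity, partial, with or without breast cancer	312300	X-linked recessive	false	false
AR	androgen insensitivity	300068	X-linked recessive	false	false
AR	hypospadias 1, X-linked	300633	X-linked recessive	false	false
AR	susceptibility to: prostate cancer	176807	autosomal dominant, somatic mutation	true	false
ATN1	congenital hypotonia, epilepsy, developmental delay, and digital anomalies	618494	autosomal dominant	false	false
ATXN2	susceptibility to: amyotrophic lateral sclerosis	183090	autosomal dominant	true	true
ATXN2	susceptibility to: Parkinson disease, late-onset	168600	autosomal dominant, multifactorial	true	true
CACNA1A	developmental and epileptic encephalopathy 42	617106	autosomal dominant	false	false
CACNA1A	episodic ataxia, type 2	108500	autosomal dominant	false	true
CACNA1A	migraine, familial hemiplegic, 1, with progressive cerebellar ataxia	141500	autosomal dominant	false	false
HTT	Lopes-Maciel-Rodan syndrome	617435	autosomal recessive	false	false
TBP	susceptibility to: Parkinson disease	168600	autosomal dominant, multifactorial	true	true
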