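snp_id	risk_allele	freq	freq_all	or_het	or_hom	source
rs1820453	G	0.239	0.374	1.49	1.65	published GWAS
rs716274	G	0.25	0.438	1.83	2.96	published GWAS
rs9981861	G	0.125	0.332	1.33	NA	published GWAS
rs16951095	C	0.805	0.917	1.3	NA	published GWAS
rs1051730	T	0.037	0.185	1.31	NA	published GWAS
rs402710	C	0.733	0.657	1.18	NA	published GWAS
rs2808630	G	0.22	0.211	1.22	NA	published GWAS
rs7626795	G	0.207	0.246	1.16	NA	published GWAS
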