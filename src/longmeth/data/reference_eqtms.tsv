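dmr_id	chrom	dmr_start	dmr_stop	n_probes	gene_symbol	ensembl_id	strand	gene_start	gene_end	spearman_rho	fdr_p
dDMR1	chr20	57426538	57427974	29	GNAS	ENSG00000087460	1	57414773	57486247	0.559	0.0667
dDMR1	chr20	57426538	57427974	29	ATP5E	ENSG00000124172	-1	57600522	57607437	0.557	0.0667
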