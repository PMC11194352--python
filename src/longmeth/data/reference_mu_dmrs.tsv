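dmr_id	chrom	start	stop	gene	n_probes	sidak_p	leading_cpg	median_PvR	median_RvM	median_PvM	unanimous_contrast
mDMR1	chr1	180922636	180923341	RP11-46A10.4;RP11-46A10.5	4	1.38e-05	cg00579423	0.09	0.37	0.46	1
mDMR2	chr10	99338056	99338241	ANKRD2	4	1.75e-04	cg27469738	-0.11	0.26	0.17	1
mDMR3	chr10	52008360	52008906	ASAH2	4	6.45e-03	cg24123634	-0.07	-0.02	-0.11	1
mDMR4	chr12	2943902	2944481	NRIP2;ITFG2	4	7.06e-03	cg02852959	-0.15	0.19	0.04	1
mDMR5	chr12	75784855	75785098	GLIPR1L2;CAPS2	6	7.59e-03	cg12351126	0.10	0.24	0.34	1
mDMR6	chr12	51566379	51567113	TFCP2	7	1.24e-02	cg19016289	0.05	0.15	0.2	1
mDMR7	chr1	1289835	1290713	MXRA8	6	1.61e-02	cg07284273	-0.16	0.33	0.15	1
mDMR8	chr15	72766637	72767333	ARIH1;RP11-1007O24.3	4	1.93e-02	cg26880891	0.09	0.02	0.14	1
mDMR9	chr19	45206843	45207560	CEACAM16	4	2.78e-02	cg24091949	-0.09	-0.04	-0.13	1
mDMR10	chr19	2250901	2251068	AMH	4	2.83e-02	cg23218559	-0.18	0.38	0.21	1
mDMR11	chr18	7567426	7568266	PTPRM	5	3.44e-02	cg05870479	0.09	0.04	0.11	1
mDMR12	chr15	85524778	85525674	PDE8A	4	4.02e-02	cg02839273	0.05	0.05	0.13	1
mDMR13	chr2	85765644	85766105	MAT2A	4	4.39e-02	cg06978067	0.08	0.05	0.13	1
mDMR14	chr19	48048129	48049234	ZNF541	4	4.90e-02	cg22341310	-0.12	0.17	0.06	1
mDMR15	chr4	4861683	4862241	MSX1	4	5.94e-02	cg11930592	0.12	-0.04	0.08	1
mDMR16	chr11	598325	599091	PHRF1	5	7.14e-02	cg12921473	-0.06	-0.05	-0.10	1
mDMR17	chr5	101119084	101119767	OR7H2P	4	7.67e-02	cg12197752	0.09	0.18	0.29	1
mDMR18	chr13	42031761	42032737	C13orf15;RGCC	4	8.16e-02	cg18495682	0.06	0.02	0.09	1
mDMR19	chr3	38206610	38207525	OXSR1	4	8.20e-02	cg19728055	0.07	0.05	0.11	1
mDMR20	chr10	14372431	14372914	FRMD4A	5	8.45e-02	cg05755354	-0.16	-0.02	-0.18	1
mDMR21	chr8	145550361	145551157	DGAT1	5	8.72e-02	cg11127482	0.06	0.04	0.11	1
mDMR22	chr11	128693473	128694916	FLI1;KCNJ1	9	9.44e-02	cg15509024	-0.12	-0.09	-0.18	1
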