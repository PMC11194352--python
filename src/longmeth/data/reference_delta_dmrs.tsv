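dmr_id	chrom	start	stop	gene	n_probes	sidak_p	leading_cpg	slope_pct_reverter	slope_pct_progressor	slope_pct_maintainer	median_slope_reverter	median_slope_progressor	median_slope_maintainer
dDMR1	chr20	57426538	57427974	GNAS;GNASAS;GNAS-AS1	29	8.33e-05	cg26496204	0.69	1.00	1.00	0.01	-0.03	-0.05
dDMR2	chr20	36148604	36149751	BLCAP;NNAT	30	1.37e-04	cg24675557	1.00	0.80	0.80	0.05	-0.02	-0.02
dDMR3	chr1	75198582	75199118	TYW3;CRYZ;RP11-17E13.3	8	3.40e-03	cg00121533	1.00	0.88	1.00	0.06	0.04	-0.08
dDMR4	chr14	101291068	101293727	MEG3	25	6.74e-03	cg14034270	0.96	0.85	1.00	0.02	-0.02	-0.02
dDMR5	chr11	1296469	1297386	TOLLIP	7	1.81e-02	cg11095027	0.86	0.57	1.00	0.03	0.03	-0.07
dDMR6	chr15	91473059	91473570	UNC45A	8	2.00e-02	cg03291024	0.75	1.00	1.00	0.01	0.09	-0.09
dDMR7	chr5	1245669	1246292	SLC6A18	4	3.38e-02	cg09075844	1.00	1.00	1.00	-0.03	0.03	-0.06
dDMR8	chr6	170597377	170597899	DLL1	4	3.66e-02	cg05228964	0.50	1.00	1.00	0.005	0.10	-0.04
dDMR9	chr6	28945322	28945493	RN7SL471P	4	6.09e-02	cg10919664	1.00	1.00	1.00	0.07	0.06	-0.16
dDMR10	chr6	27647713	27648355	RP1-15D7.1	4	7.14e-02	cg25106913	0.75	0.75	1.00	0.005	0.06	-0.05
dDMR11	chr5	1867978	1868694	IRX4	6	8.71e-02	cg14773178	0.83	1.00	1.00	0.04	0.08	-0.08
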