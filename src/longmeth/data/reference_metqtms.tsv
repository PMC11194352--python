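dmr_id	chrom	dmr_start	dmr_stop	metabolite	standardized_beta	fdr_p
dDMR2	chr20	36148604	36149751	TG (49:2)	0.320	0.0992
dDMR5	chr11	1296469	1297386	TG (53:2)	0.411	0.0121
dDMR5	chr11	1296469	1297386	Phosphatidylcholine (33:1)	0.361	0.0469
dDMR5	chr11	1296469	1297386	TG (53:3)	0.353	0.0627
dDMR5	chr11	1296469	1297386	PE (38:4)	0.339	0.0826
dDMR5	chr11	1296469	1297386	TG (49:2)	0.330	0.0948
dDMR5	chr11	1296469	1297386	TG (47:0)	0.329	0.0952
dDMR5	chr11	1296469	1297386	TG (51:3)	0.327	0.0954
dDMR5	chr11	1296469	1297386	PC (33:1)	0.327	0.0954
dDMR5	chr11	1296469	1297386	Phosphatidylcholines (35:1)	0.325	0.0954
dDMR5	chr11	1296469	1297386	TG (53:1)	0.320	0.0992
dDMR8	chr6	170597377	170597899	Phosphatidylcholine (35:4)	0.438	0.0078
dDMR8	chr6	170597377	170597899	Phosphatidylcholines (33:1)	0.404	0.0121
dDMR8	chr6	170597377	170597899	Phosphatidylcholines (33:0)	0.403	0.0121
dDMR8	chr6	170597377	170597899	Phosphatidylcholines (33:1) B	0.402	0.0121
dDMR8	chr6	170597377	170597899	Phosphatidylcholines (35:3)	0.396	0.0138
dDMR8	chr6	170597377	170597899	LPC (15:0)	0.393	0.0139
dDMR8	chr6	170597377	170597899	Phosphatidylcholines (38:5)	0.375	0.0527
dDMR8	chr6	170597377	170597899	Phosphatidylcholines (33:2)	0.366	0.0445
dDMR8	chr6	170597377	170597899	Phosphatidylcholines (35:4) B	0.365	0.0445
dDMR8	chr6	170597377	170597899	Phosphatidylcholines (31:0)	0.350	0.0647
dDMR8	chr6	170597377	170597899	Phosphatidylcholines (35:1)	0.347	0.0647
dDMR8	chr6	170597377	170597899	Phosphatidylcholines (36:3)	0.347	0.0647
dDMR8	chr6	170597377	170597899	Phosphatidylcholines (p-34:0) or Phosphatidylcholines (o-34:1)	-0.334	0.0940
dDMR8	chr6	170597377	170597899	TG (49:3)	0.332	0.0940
dDMR8	chr6	170597377	170597899	Phosphatidylcholines (33:2) B	0.332	0.0940
dDMR8	chr6	170597377	170597899	Phosphatidylcholines (36:3) B	0.325	0.0954
dDMR8	chr6	170597377	170597899	Phosphatidylcholines (37:6)	0.324	0.0954
dDMR8	chr6	170597377	170597899	Phosphatidylcholines (35:1) B	0.323	0.0975
dDMR9	chr6	28945322	28945493	Phosphatidylcholine (p-38:2) or Phosphatidylcholine (o-38:3)	0.345	0.0662
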