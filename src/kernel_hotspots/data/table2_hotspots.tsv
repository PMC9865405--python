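hotspot_id	chrom	start	end	n_clusters	clusters	n_genes	genes
HS01	1	12622245	17191112	3	KW-gCL1-1,KW-qCL1-1,HKW-qCL1-1	0	
HS02	1	20505000	52520534	14	KW-qCL1-2,HKW-qCL1-2,KT-qCL1-1,KL-gCL1-1,KT-gCL1-1,KT-qCL1-2,KT-qCL1-3,HKW-gCL1-1,KW-gCL1-2,KT-qCL1-4,KT-gCL1-2,KT-qCL1-5,KT-qCL1-6,KT-qCL1-7	4	Emp602,Urb2,Ppr22,Dek1
HS03	1	53029436	59415031	3	KW-gCL1-3,KL-qCL1-1,HKW-qCL1-2	1	Ppr27
HS04	1	211711329	221020719	3	KL-gCL1-2,KT-qCL1-9,HKW-qCL1-4	0	
HS05	1	238107995	242396593	4	KL-gCL1-3,KL-qCL1-2,KT-qCL1-11,KW-qCL1-5	0	
HS06	1	244038128	252279335	6	KW-qCL1-5,HKW-qCL1-5,KL-qCL1-3,KW-gCL1-5,KW-qCL1-6,HKW-qCL1-6	0	
HS07	1	270393381	288290428	6	KL-qCL1-3,KT-gCL1-3,KW-gCL1-6,KT-qCL1-15,KT-qCL1-16,HKW-gCL1-3	6	Dek35,Emp4,Emp10,MPPR6,Lem1,Emp18
HS08	2	1645703	3317858	3	KL-qCL2-1,HKW-qCL2-1,KT-qCL2-1	0	
HS09	2	19436743	33434209	5	KW-qCL2-1,HKW-qCL2-7,KT-qCL2-3,KW-qCL2-2,KW-qCL2-3	0	
HS10	2	193515365	196000000	3	KW-qCL2-5,KL-qCL2-4,HKW-qCL2-11	1	Emp6
HS11	3	1325039	3615750	8	KW-gCL3-1,KT-gCL3-1,KL-gCL3-1,KW-qCL3-1,KL-qCL3-1,KL-qCL3-2,KW-qCL3-2,HKW-qCL3-1	0	
HS12	3	4388286	6099395	5	KL-gCL3-1,KW-qCL3-3,HKW-qCL3-2,KT-qCL3-1,KW-qCL3-4	0	
HS13	4	3561183	6010197	3	KL-qCL4-1,HKW-gCL4-1,KW-gCL4-1	0	
HS14	4	158189789	163298733	4	KW-gCL4-4,HKW-gCL4-4,KW-qCL4-2,KL-gCL4-3	0	
HS15	4	175915845	193659742	8	KT-gCL4-1,HKW-gCL4-5,HKW-qCL4-3,KL-gCL4-4,KW-qCL4-3,KL-qCL4-3,KW-qCL4-4,KW-gCL4-5	3	O1,Dek15,Emp11
HS16	4	196013048	201338547	3	HKW-qCL4-4,KW-qCL4-6,KW-gCL4-5	0	
HS17	4	237957206	240000000	3	KW-qCL4-7,KW-gCL4-6,HKW-qCL4-6	0	
HS18	5	14156572	16289485	3	KW-qCL5-1,HKW-qCL5-2,KL-gCL5-1	0	
HS19	5	34324375	65639673	4	KW-qCL5-2,KW-gCL5-2,KW-gCL5-3,HKW-qCL5-2	2	Dek36,Dek55
HS20	5	188839192	195089478	5	HKW-qCL5-6,HKW-qCL5-5,KW-gCL5-5,KT-gCL5-2,KL-gCL5-4	0	
HS21	5	196011766	199615219	3	KW-qCL5-3,HKW-qCL5-7,KL-qCL5-2	0	
HS22	5	202544328	209785812	5	HKW-qCL5-11,HKW-qCL5-10,KL-gCL5-5,HKW-qCL5-9,KW-qCL5-4	0	
HS23	5	211000000	212583743	3	HKW-qCL5-12,KT-gCL5-3,KL-gCL5-5	0	
HS24	7	112866130	118353636	3	HKW-qCL7-3,KL-qCL7-1,KL-gCL7-1	0	
HS25	7	125132474	129166008	4	HKW-qCL7-3,KL-gCL7-2,KW-qCL7-1,KW-qCL7-2	0	
HS26	7	132311932	156631694	11	HKW-gCL7-1,KW-qCL7-4,KL-gCL7-3,KL-qCL7-2,KL-qCL7-3,KL-qCL7-4,KW-qCL7-5,KW-gCL7-1,KW-qCL7-6,KW-qCL7-7,HKW-qCL7-3	2	Dek41,Dek47
HS27	7	172547374	174900000	4	HKW-qCL7-5,KT-gCL7-2,KL-gCL7-4,KL-qCL7-8	0	
HS28	8	167000000	170036314	3	KW-qCL8-2,KL-qCL8-3,HKW-qCL8-2	0	
HS29	9	149400961	157000000	9	HKW-qCL9-2,KL-gCL9-1,KW-qCL9-2,HKW-gCL9-2,KW-qCL9-3,KT-gCL9-1,KL-qCL9-8,KW-qCL9-4,KW-qCL9-5	1	qKW9
HS30	10	109814884	122563176	3	HKW-gCL10-1,KW-gCL10-2,HKW-qCL10-1	1	Smk6
HS31	10	130739025	149279019	10	HKW-qCL10-2,KW-gCL10-3,HKW-gCL10-2,KL-gCL10-1,KT-gCL10-1,HKW-qCL10-3,KW-qCL10-1,HKW-qCL10-4,KL-qCL10-1,HKW-qCL10-5	1	Nkd2
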