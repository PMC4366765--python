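protein_name	accession	fold_change	p_value	f_value	sham_1	sham_2	sham_3	uuo3w_1	uuo3w_2	uuo3w_3
Alpha-actinin-1	ACTN1_RAT	14.00	0	78.11	0	2	0	8	10	10
Alpha-actinin-4	ACTN4_RAT	2.90	0.017	12.02	4	3	3	6	14	9
Annexin A1	ANXA1_RAT	5.96	0.001	25.10	2	11	10	47	47	43
Cluster of Histone H1.4	H14_RAT	20.00	0.001	22.47	0	2	0	13	18	9
Cluster of Vimentin	VIME_RAT	6.00	0	183.77	2	5	2	17	19	18
Clusterin	CLUS_RAT	2.90	0.006	10.69	32	31	35	79	117	87
Complement component C9	CO9_RAT	2.16	0.015	6.76	18	40	37	67	68	70
Extracellular superoxide dismutase [Cu-Zn]	SODE_RAT	9.00	0.005	10.85	0	2	0	6	7	5
Glycogen phosphorylase, muscle form	PYGM_RAT	38.00	0	35.85	1	0	0	10	14	14
Golgi resident protein GCP60	GCP60_RAT	29.00	0	34.68	0	1	0	12	10	7
Ig gamma-1 chain C region	IGHG1_RAT	2.43	0.007	8.60	9	11	8	29	18	21
Lumican	LUM_RAT	3.40	0.003	12.69	5	3	2	12	9	13
Moesin	MOES_RAT	18.00	0.01	7.12	2	0	0	9	18	9
Periaxin	PRAX_RAT	38.00	0.002	13.57	1	0	0	9	14	15
Protein S100-A8	S10A8_RAT	9.50	0.002	13.94	1	3	0	16	14	8
Protein S100-A9	S10A9_RAT	16.50	0.001	20.45	0	2	0	10	12	11
Serine protease inhibitor A3N	SPA3N_RAT	2.83	0.006	8.46	32	92	67	181	196	163
Transaldolase	TALDO_RAT	6.00	0.034	27.32	2	3	0	10	9	11
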