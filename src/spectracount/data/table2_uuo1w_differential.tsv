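protein_name	accession	fold_change	p_value	f_value	sham_1	sham_2	sham_3	uuo1w_1	uuo1w_2	uuo1w_3
Aminopeptidase N	AMPN_RAT	2.94	0.002	26.925	15	13	7	41	25	37
Cathepsin D	CATD_RAT	4.98	0.01	9.528	8	39	10	106	51	127
Galectin-3-binding protein	LG3BP_RAT	5.20	0.01	8.212	10	9	1	41	20	43
Glycogen phosphorylase, muscle form	PYGM_RAT	32.00	0.001	35.848	1	0	0	12	12	8
Intraflagellar transport protein 172 homolog	IF172_RAT	29.00	0.005	9.349	0	0	1	14	10	5
Protein S100-A9	S10A9_RAT	12.50	0.004	20.447	0	2	0	7	6	12
Solute carrier family 12 member 7	S12A7_RAT	24.00	0.008	7.879	1	0	0	6	11	7
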