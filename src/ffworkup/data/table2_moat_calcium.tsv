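cohort	patient_id	moat_two_cell	moat_mii	moat_group_label	moca_n	moca_mean_axf	hoca_n	hoca_mean_axf
1	P2	5	26	1	17	2.15	10	0.00
1	P3	8	20	2
1	P4	21	27	2
1	P7	26	31	2	15	2.03	7	0.00
1	P9	20	24	2	16	10.35	8	0.10
1	P15	7	14	2
1	P18	13	24	2	11	39.17	14	0.60
1	P20	14	22	2	11	12.40	10	0.00
1	P21	17	19	3	10	13.00	13	0.00
1	P23	22	28	2	11	18.93	9	0.00
1	P26	26	29	3	7	33.24	8	0.00
2	P29	8	31	1-2	18	0.15	10	0.00
2	P32	26	28	3	14	94.63	11	3.24
2	P34	28	32	3	16	15.53	13	0.00
2	P35	19	24	2	16	22.02	9	0.00
2	P36	30	30	3	10	18.17	10	0.00
2	P44	20	25	2
2	P46	8	31	1-2	17	0.53	10	0.00
2	P54	3	42	1	14	1.08	11	0.00
	CONTROL	464	496		42	85.71	58	3.88
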