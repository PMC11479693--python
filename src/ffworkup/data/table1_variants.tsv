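cohort	patient_id	gene	transcript	exon	cdna_change	protein_change	zygosity	rsid	gnomad_af	revel	alphamissense	consequence	pre_posterior	pre_label	post_posterior	post_label
1	P2	PLCZ1	NM_033123.4	6	c.698A>T	p.His233Leu	het	rs200061726	0.0009183	0.256	0.171	missense	0.988	LP	0.994	P
1	P2	PLCZ1	NM_033123.4	9	c.964A>T	p.Lys322*	het		0.00000159			nonsense	0.9	LP	0.949	LP
1	P3	PLCZ1	NM_033123.4	13	c.1499C>T	p.Ser500Leu	het	rs10505830	0.04151	0.099	0.086	missense	0.812	VUS (hot)	0.9	LP
1	P4	PLCZ1	NM_033123.4	13	c.1499C>T	p.Ser500Leu	het	rs10505830	0.04151	0.099	0.086	missense	0.812	VUS (hot)	0.9	LP
1	P7	PLCZ1	NM_033123.4	13	c.1499C>T	p.Ser500Leu	hom	rs10505830	0.04151	0.099	0.086	missense	0.812	VUS (hot)	0.9	LP
1	P9	PLCZ1	NM_033123.4	5	c.422G>A	p.Arg141His	het	rs202034240	0.00002366	0.059	0.074	missense	0.5	VUS (tepid)	0.675	VUS (warm)
1	P15	PLCZ1	NM_033123.4	13	c.1499C>T	p.Ser500Leu	het	rs10505830	0.04151	0.099	0.086	missense	0.812	VUS (hot)	0.9	LP
1	P18	PLCZ1	NM_033123.4	13	c.1499C>T	p.Ser500Leu	hom	rs10505830	0.04151	0.099	0.086	missense	0.812	VUS (hot)	0.9	LP
1	P20	PLCZ1	NM_033123.4	13	c.1499C>T	p.Ser500Leu	hom	rs10505830	0.04151	0.099	0.086	missense	0.812	VUS (hot)	0.9	LP
1	P21	PLCZ1	NM_033123.4	6	c.698A>T	p.His233Leu	het	rs200061726	0.0009183	0.256	0.171	missense	0.988	LP	0.994	P
1	P23	PLCZ1	NM_033123.4	13	c.1499C>T	p.Ser500Leu	hom	rs10505830	0.04151	0.099	0.086	missense	0.812	VUS (hot)	0.9	LP
1	P26	PLCZ1	NM_033123.4	13	c.1499C>T	p.Ser500Leu	het	rs10505830	0.04151	0.099	0.086	missense	0.812	VUS (hot)	0.9	LP
1	P26	PLCZ1	NM_033123.4	4	c.280C>T	p.Gln94*	het	rs138801851	0.0001370			nonsense	0.9	LP	0.949	LP
2	P29	ACTL7A	NM_006687.4	1	c.1088dup	p.Ser364Glnfs*9	hom	rs752334307	0.00006134			frameshift	0.949	LP	0.997	P
2	P32	PLCZ1	NM_033123.4	4	c.221T>C	p.Ile74Thr	het	rs145549980	0.0002654	0.045	0.068	missense	0.5	VUS (tepid)	0.5	VUS (tepid)
2	P32	ACTL7A	NM_006687.4	1	c.547T>C	p.Tyr183His	het	rs41278345	0.002240	0.704	0.880	missense	0.812	VUS (hot)	0.675	VUS (warm)
2	P34	PLCZ1	NM_033123.4	6	c.698A>T	p.His233Leu	het	rs200061726	0.0009183	0.256	0.171	missense	0.988	LP	0.994	P
2	P34	ACTL9	NM_178525.5	1	c.812G>C	p.Arg271Pro	het	rs73507819	0.02063	0.185	0.287	missense	0.188	VUS (cool)	0.188	VUS (cool)
2	P35	PLCZ1	NM_033123.4	6	c.698A>T	p.His233Leu	het	rs200061726	0.0009183	0.256	0.171	missense	0.988	LP	0.994	P
2	P36	PLCZ1	NM_033123.4	10	c.1136T>C	p.Ile379Thr	het	rs201548309	0.00005206	0.442	0.533	missense	0.812	VUS (hot)	0.9	LP
2	P44	PLCZ1	NM_033123.4	6	c.698A>T	p.His233Leu	het	rs200061726	0.0009183	0.256	0.171	missense	0.988	LP	0.994	P
2	P46	ACTL7A	NM_006687.4	1	c.640G>A	p.Gly214Ser	hom	rs41278347	0.005301	0.891	0.798	missense	0.5	VUS (tepid)	0.5	VUS (tepid)
2	P46	ACTL7A	NM_006687.4	1	c.1117C>T	p.Arg373Cys	hom	rs775405375	0.00002540	0.910	0.947	missense	0.994	P	0.994	P
2	P54	ACTL7A	NM_006687.4	1	c.1018G>A	p.Val340Met	het	rs7872077	0.01517	0.197	0.113	missense	0.188	VUS (cold)	0.325	VUS (cool)
2	P54	ACTL7A	NM_006687.4	1	c.657G>A	p.Val219=	het	rs3739693	0.01408			synonymous	0.1	VUS (ice cold)	0.188	VUS (cold)
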