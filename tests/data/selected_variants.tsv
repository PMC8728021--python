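# Selected enrichment-driving variants, by group, tier and pathway.
# The ref/alt allele columns are placeholders consistent with the HGVS change
# (the source report prints only the transcript change, not VCF alleles).
group	tier	pathway_id	pathway_name	patient_id	gene_symbol	entrez_id	exon_change	rsid	qual	depth	chrom	pos	consequence	impact_score	cadd_phred	ref	alt
NoSTox	functional	R-HSA-74751	Insulin receptor signaling cascade	21	MAPK3	5595	1/c.38_39insC	NA	44	104	chr16	30123171	frameshift insertion	NA	NA	A	AC
NoSTox	functional	R-HSA-74751	Insulin receptor signaling cascade	39	MAPK3	5595	1/c.37_38insC	NA	206	175	chr16	30123172	frameshift insertion	NA	NA	G	GC
NoSTox	functional	R-HSA-74751	Insulin receptor signaling cascade	43	MAPK3	5595	1/c.37_38insC	NA	58	110	chr16	30123172	frameshift insertion	NA	NA	G	GC
NoSTox	functional	R-HSA-74751	Insulin receptor signaling cascade	16	PDE3B	5140	1/c.C447A	NA	307	116	chr11	14644522	stopgain	1	35	C	A
NoSTox	functional	R-HSA-5357956	TNFR1-induced NFkB signaling pathway	74	UBC	7316	2/c.2051dupG	NA	1343	198	chr12	124911720	frameshift insertion	NA	NA	T	TG
NoSTox	functional	R-HSA-844615	The AIM2 inflammasome	16	AIM2	9477	5/c.712delA	NA	642	90	chr1	159062697	frameshift deletion	NA	NA	CA	C
NoSTox	impact	R-HSA-844615	The AIM2 inflammasome	84	PYCARD	29108	2/c.C278G	NA	179	96	chr16	31202200	nonsynonymous SNV	1	10.47	C	G
NoSTox	impact	R-HSA-75896	Plasmalogen biosynthesis	50	GNPAT	8443	9/c.G1300A	rs11122266	364	158	chr1	231270961	nonsynonymous SNV	3	19.66	G	A
NoSTox	impact	R-HSA-75896	Plasmalogen biosynthesis	66	GNPAT	8443	9/c.C1240T	rs767514222	460	205	chr1	231270901	nonsynonymous SNV	3	14.27	C	T
NoSTox	impact	R-HSA-75896	Plasmalogen biosynthesis	88	AGPS	8540	c.A83T	rs764286061	135	97	chr2	177392872	nonsynonymous SNV	5	15.41	A	T
STox	functional	R-HSA-75205	Dissolution of fibrin clot	2	SERPINF2	5345	4/c.C169T	rs374446894	379	196	chr17	1745399	stopgain	1	17.8	C	T
STox	impact	R-HSA-77042	Formation of editosomes by ADAR proteins	94	ADAR	103	2/c.C577G	NA	467	261	chr1	154602065	nonsynonymous SNV	7	23.9	C	G
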