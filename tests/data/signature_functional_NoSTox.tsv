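DB_ID	Pathway name	Patient ID#	Number of patients
R-HSA-73776	RNA polymerase II promoter escape	x7,x22,x55	3
R-HSA-73779	RNA polymerase II transcription preinitiation and promoter opening	x7,x22,x55	3
R-HSA-75953	RNA polymerase II transcription initiation	x7,x22,x55	3
R-HSA-76042	RNA polymerase II transcription initiation and promoter clearance	x7,x22,x55	3
R-HSA-72200	mRNA editing: C to U conversion	x9,x49,x29	3
R-HSA-75072	mRNA editing	x9,x49,x29	3
R-HSA-75094	Formation of the editosome	x9,x49,x29	3
R-HSA-73780	RNA polymerase III chain elongation	x10	1
R-HSA-73980	RNA polymerase III transcription termination	x10	1
R-HSA-74158	RNA polymerase III transcription	x10,x32	2
R-HSA-749476	RNA polymerase III abortive and retractive initiation	x10,x32	2
R-HSA-76046	RNA polymerase III transcription initiation	x10,x32	2
R-HSA-76061	RNA polymerase III transcription initiation from type 1 promoter	x10,x32	2
R-HSA-76066	RNA polymerase III transcription initiation from type 2 promoter	x10,x32	2
R-HSA-76071	RNA polymerase III transcription initiation from type 3 promoter	x10,x32	2
R-HSA-8850843	Phosphate bond hydrolysis by NTPDase proteins	x14	1
R-HSA-75105	Fatty acyl-CoA biosynthesis	x15	1
R-HSA-73728	RNA polymerase I promoter opening	x21,x39,x43	3
R-HSA-74749	Signal attenuation	x21,x39,x43	3
R-HSA-74751	Insulin receptor signaling cascade	x21,x39,x43,x16	4
R-HSA-879415	Advanced glycosylation endproduct receptor signaling	x21,x39,x43	3
R-HSA-881907	Gastrin-CREB signaling pathway via PKC and MAPK	x21,x39,x43	3
R-HSA-8853659	RET signaling	x21,x50	2
R-HSA-77075	RNA Pol II CTD phosphorylation and interaction with CE	x22,x55	2
R-HSA-879518	Transport of organic anions	x43,x48	2
R-HSA-8852405	Signaling by MST1	x43,x48,x79	3
R-HSA-73942	DNA damage reversal	x62,x82,x85	3
R-HSA-73943	Reversal of alkylation damage by DNA dioxygenases	x62,x82,x85	3
R-HSA-75109	Triglyceride biosynthesis	x62,x77,x96	3
R-HSA-8848021	Signaling by PTK6	x62,x74	2
R-HSA-8849474	PTK6 activates STAT3	x62	1
R-HSA-5357956	TNFR1-induced NFkappaB signaling pathway	x74	1
R-HSA-5358346	Hedgehog ligand biogenesis	x74	1
R-HSA-5362768	Hh mutants that do not undergo autocatalytic processing are degraded by ERAD	x74	1
R-HSA-73893	DNA damage bypass	x74,x37	2
R-HSA-75815	Ubiquitin-dependent degradation of Cyclin D	x74	1
R-HSA-8849469	PTK6 regulates RTKs and their effectors AKT1 and DOK1	x74	1
R-HSA-8852276	The role of GTSE1 in G2/M progression after G2 checkpoint	x74,x29	2
R-HSA-8854050	FBXL7 downregulates AURKA during mitotic entry and in early mitosis	x74	1
R-HSA-75035	Chk1/Chk2(Cds1)-mediated inactivation of cyclin B:Cdk1 complex	x84	1
R-HSA-73614	Pyrimidine salvage	x87	1
R-HSA-804914	Transport of fatty acids	x87	1
R-HSA-73843	5-Phosphoribose 1-diphosphate biosynthesis	x92,x37,x69	3
R-HSA-844615	The AIM2 inflammasome	x16	1
R-HSA-8862803	Deregulated CDK5 triggers multiple neurodegenerative pathways in Alzheimer's disease models	x56	1
R-HSA-72764	Eukaryotic translation termination	x88	1
R-HSA-5358493	Synthesis of diphthamide-EEF2	x96	1
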