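DB_ID	Pathway name	Patient ID#	Number of patients
R-HSA-75035	Chk1/Chk2(Cds1)-mediated inactivation of cyclin B:Cdk1 complex	x14,x15,x19,x31,x43,x48,x84, x85,x87,x37,x50	11
R-HSA-8849469	PTK6 regulates RTKs and their effectors AKT1 and DOK1	x14,x62,x55,x88	4
R-HSA-202403	TCR signaling	x31	1
R-HSA-202424	Downstream TCR signaling	x31,x16	2
R-HSA-202427	Phosphorylation of CD3 and TCR zeta chains	x31,x16	2
R-HSA-202430	Translocation of ZAP-70 to immunological synapse	x31,x85,x16	3
R-HSA-202433	Generation of second messenger molecules	x31,x16	2
R-HSA-388841	Costimulation by the CD28 family	x31	1
R-HSA-389948	PD-1 signaling	x31,x16	2
R-HSA-8853336	Signaling by plasma membrane FGFR1 fusions	x39,x52,x56	3
R-HSA-8849474	PTK6 activates STAT3	x62,x55	2
R-HSA-198933	Immunoregulatory interactions between a lymphoid and a nonlymphoid cell	x74	1
R-HSA-6805567	Keratinization	x84	1
R-HSA-844615	The AIM2 inflammasome	x84	1
R-HSA-75896	Plasmalogen biosynthesis	x50,x66,x88	3
R-HSA-8849468	PTK6 regulates proteins involved in RNA processing	x55,x59,x88	3
R-HSA-977347	Serine biosynthesis	x71	1
R-HSA-381753	Olfactory signaling pathway	x96	1
R-HSA-8853333	Signaling by FGFR2 fusions	x96	1
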