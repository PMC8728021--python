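term	pulmonary	grade_band	early_n	early_pct	acute_n	acute_pct	late_n	late_pct
anemia	False	1-2	0	0	0	0	1	2
anemia	False	>=3	1	2	0	0	0	0
chest wall pain	False	1-2	12	24	12	24	5	10
chest wall pain	False	>=3	1	2	0	0	1	2
dermatitis	False	1-2	11	22	2	4	0	0
dermatitis	False	>=3	1	2	0	0	0	0
fatigue	False	1-2	19	39	10	20	4	8
fatigue	False	>=3	1	2	1	2	1	2
fracture	False	any	0	0	0	0	2	4
GGT	False	1-2	9	18	11	22	5	10
GGT	False	>=3	0	0	1	2	3	6
nausea/vomiting	False	1-2	23	47	1	2	1	2
nausea/vomiting	False	>=3	0	0	0	0	0	0
oesophagitis	False	1-2	34	69	6	12	1	2
oesophagitis	False	>=3	2	4	0	0	0	0
pericardial effusion	False	1-2	0	0	0	0	0	0
pericardial effusion	False	>=3	0	0	1	2	2	4
cough	True	1-2	5	10	16	33	14	29
cough	True	>=3	0	0	0	0	0	0
dyspnea	True	1-2	9	18	17	35	7	14
dyspnea	True	>=3	0	0	1	2	4	8
fibrosis	True	1-2	0	0	0	0	1	2
fibrosis	True	>=3	0	0	1	2	1	2
pneumonitis	True	1-2	1	2	1	2	1	2
pneumonitis	True	>=3	0	0	2	4	2	4
thromboembolic event	True	any	0	0	2	4	1	2
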