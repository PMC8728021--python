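patient_id	term	grade	phase
2	dyspnea	2	acute
2	pneumonitis	3	acute
2	cough	2	acute
2	thromboembolic event	3	acute
2	dyspnea	3	late
12	pneumonitis	1	early
12	fibrosis	3	acute
17	thromboembolic event	3	late
20	pneumonitis	3	late
20	cough	2	late
53	cough	2	late
53	dyspnea	2	late
53	pneumonitis	3	late
58	dyspnea	3	acute
58	cough	2	late
58	pneumonitis	3	late
58	dyspnea	3	late
61	dyspnea	2	acute
61	cough	2	late
61	dyspnea	3	late
70	dyspnea	2	early
70	pneumonitis	3	acute
70	thromboembolic event	3	acute
94	dyspnea	1	early
94	dyspnea	2	acute
94	pneumonitis	2	late
94	fibrosis	3	late
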