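DB_ID	Pathway name	Patient ID#	Number of patients
R-HSA-75064	mRNA editing: A to I conversion	x94	1
R-HSA-75102	C6 deamination of adenosine	x94	1
R-HSA-77042	Formation of editosomes by ADAR proteins	x94	1
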