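DB_ID	Pathway name	Patient ID#	Number of patients
R-HSA-75205	Dissolution of fibrin dissolution of fibrin clot	x2	1
R-HSA-72649	Translation initiation complex formation	x17,x53	2
R-HSA-72695	Formation of the ternary complex, and subsequently, the 43S complex	x53	1
R-HSA-72702	Ribosomal scanning and start codon recognition	x53	1
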