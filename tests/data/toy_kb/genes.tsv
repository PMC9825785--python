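gene_id	species_id	symbol
HG1	human	CYP19A1
HG2	human	TSPO
HG3	human	AHR
HG4	human	ESR1
CG1	celegans	cyp-19
CG2	celegans	tspo-1
CG3	celegans	tspo-2
CG4	celegans	ahr-1
ZG1	zebrafish	cyp19a1a
ZG2	zebrafish	tspo
ZG3	zebrafish	esr1
ZG4	zebrafish	ahr2
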