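phenotype_id	species_id	gene_id
WBP:0001	celegans	CG1
WBP:0001	celegans	CG2
WBP:0002	celegans	CG2
WBP:0003	celegans	CG3
WBP:0004	celegans	CG4
ZP:0001	zebrafish	ZG1
ZP:0002	zebrafish	ZG2
ZP:0002	zebrafish	ZG3
ZP:0003	zebrafish	ZG3
MP:0001	human	HG1
MP:0002	human	HG2
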