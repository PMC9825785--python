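compound_id	species_id	phenotype_id
CPD1	celegans	WBP:0001
CPD1	celegans	WBP:0002
CPD1	celegans	WBP:0003
CPD1	zebrafish	ZP:0002
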