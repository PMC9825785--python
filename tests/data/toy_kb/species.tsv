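species_id	display_name	is_mammal	is_reference
human	Homo sapiens	1	1
celegans	Caenorhabditis elegans	0	0
zebrafish	Danio rerio	0	0
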