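compound_id	target_gene_id
CPD1	HG1
CPD1	HG2
CPD2	HG4
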