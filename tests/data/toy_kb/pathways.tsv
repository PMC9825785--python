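pathway_id	name	gene_id
PWY1	Metabolism of steroids	HG1
PWY1	Metabolism of steroids	HG2
PWY2	Aryl hydrocarbon receptor signalling	HG2
PWY2	Aryl hydrocarbon receptor signalling	HG3
PWY2	Aryl hydrocarbon receptor signalling	HG4
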