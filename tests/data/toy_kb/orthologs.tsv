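human_gene_id	model_gene_id	relation
HG1	CG1	one2one
HG2	CG2	one2many
HG2	CG3	one2many
HG3	CG4	many2many
HG4	CG4	many2many
HG1	ZG1	one2one
HG2	ZG2	one2one
HG4	ZG3	one2one
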