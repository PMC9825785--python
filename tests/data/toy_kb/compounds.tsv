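compound_id	name	cas	ec	smiles	fingerprint
CPD1	diethylstilbestrol|DES	56-53-1	200-278-5	CC/C(=C(\CC)c1ccc(O)cc1)c1ccc(O)cc1	1100110011001100
CPD2	estradiol	50-28-2	200-023-8	C[C@]12CC[C@H]3[C@@H](CCc4cc(O)ccc43)[C@@H]1CC[C@@H]2O	1100110011001111
CPD3	control compound	64-17-5	200-578-6	CCO	0011001100110011
CPD4	unfingerprinted compound				
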