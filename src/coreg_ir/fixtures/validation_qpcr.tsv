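gene_id	rela_binding_confirmed	p53_binding_confirmed	sirela_direction	sitp53_direction
IL4I1	1	1	inhibited	stimulated
NFKBIA	1	0	inhibited	stimulated
CDKN1A	1	1	stimulated	inhibited
SERPINE1	1	1	stimulated	inhibited
RRAD	1	1	inhibited	inhibited
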