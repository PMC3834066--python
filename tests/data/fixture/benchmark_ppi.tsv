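id_a	id_b	label
P0002	P0003	1
P0002	P0004	1
P0001	P0003	0
P0001	P0004	0
P0003	P0004	0
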