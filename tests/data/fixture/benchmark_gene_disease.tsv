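id_a	id_b	label
P0002	D001	1
P0003	D001	0
P0004	D001	0
P0004	D002	0
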