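concept_id	name	category	planted_base_freq
P0001	protein 1	protein	
P0002	protein 2	protein	
P0003	protein 3	protein	
P0004	protein 4	protein	
D001	disease 1	disease	
D002	disease 2	disease	
C00001	context term 1	context	
C00002	context term 2	context	
G01	protein binding	generic	0.6
G02	mutation abnormality	generic	0.3
G03	generic term 3	generic	0.19999999999999998
N0001	incidental term 1	noise	
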