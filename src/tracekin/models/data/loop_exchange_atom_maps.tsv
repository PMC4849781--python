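reaction_id	substrate	sub_carbon	product	prod_carbon
exch	A#1	1	B#1	1
exch	A#1	2	B#1	2
exch	B#1	1	A#1	1
exch	B#1	2	A#1	2
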