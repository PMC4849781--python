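reaction_id	substrate	sub_carbon	product	prod_carbon
r1	A#1	1	B#1	1
r1	A#1	2	B#1	2
r1	A#1	3	B#1	3
r2	B#1	1	C#1	1
r2	B#1	2	C#1	2
r2	B#1	3	C#1	3
r3	C#1	1	OUT#1	1
r3	C#1	2	OUT#1	2
r3	C#1	3	OUT#1	3
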