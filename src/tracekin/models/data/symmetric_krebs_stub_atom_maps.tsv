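reaction_id	substrate	sub_carbon	product	prod_carbon
feed	SRC#1	1	fum#1	1
feed	SRC#1	2	fum#1	2
feed	SRC#1	3	fum#1	3
feed	SRC#1	4	fum#1	4
fh	fum#1	1	mal#1	1
fh	fum#1	2	mal#1	2
fh	fum#1	3	mal#1	3
fh	fum#1	4	mal#1	4
out	mal#1	1	OUT#1	1
out	mal#1	2	OUT#1	2
out	mal#1	3	OUT#1	3
out	mal#1	4	OUT#1	4
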