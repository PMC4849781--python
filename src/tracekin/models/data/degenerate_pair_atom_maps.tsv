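reaction_id	substrate	sub_carbon	product	prod_carbon
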