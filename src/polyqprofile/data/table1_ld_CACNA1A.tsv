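id_a	id_b	r2
rs5021328	rs16003	0.133856
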