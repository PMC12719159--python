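id_a	id_b	r2
rs653178	rs848130	0.065999
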