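id_a	id_b	r2
rs832190	rs3821902	0.081268
rs832190	rs13434089	0.072432
rs3821902	rs13434089	0.068201
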