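id_a	id_b	r2
rs363096	rs61348208	0.11382
rs363096	rs7685686	0.149146
rs363096	rs82334	0.059673
rs363096	rs2071703	0.10067
rs363096	rs113928896	0.089644
rs363096	rs362307	0.070602
rs363096	rs6828882	0.138337
rs363096	rs2798297	0.104048
rs61348208	rs7685686	0.81122
rs61348208	rs82334	0.778536
rs61348208	rs2071703	0.805606
rs61348208	rs113928896	0.123368
rs61348208	rs362307	0.069888
rs61348208	rs6828882	0.076476
rs61348208	rs2798297	0.082546
rs7685686	rs82334	0.801433
rs7685686	rs2071703	0.795587
rs7685686	rs113928896	0.099443
rs7685686	rs362307	0.11015
rs7685686	rs6828882	0.128661
rs7685686	rs2798297	0.12351
rs82334	rs2071703	0.810574
rs82334	rs113928896	0.130202
rs82334	rs362307	0.08801
rs82334	rs6828882	0.085164
rs82334	rs2798297	0.071946
rs2071703	rs113928896	0.12239
rs2071703	rs362307	0.087699
rs2071703	rs6828882	0.087691
rs2071703	rs2798297	0.113894
rs113928896	rs362307	0.084841
rs113928896	rs6828882	0.117772
rs113928896	rs2798297	0.111233
rs362307	rs6828882	0.100691
rs362307	rs2798297	0.11413
rs6828882	rs2798297	0.113317
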