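id_a	id_b	r2
rs719316	rs17603856	0.144353
rs719316	rs909788	0.085942
rs719316	rs6459480	0.128481
rs719316	rs9297016	0.109128
rs719316	rs7772172	0.079433
rs719316	rs6459472	0.142273
rs719316	rs9367926	0.136933
rs719316	rs6915310	0.086414
rs719316	rs2237199	0.147318
rs719316	rs7770062	0.072452
rs719316	rs73366713	0.13055
rs719316	rs3819405	0.11809
rs17603856	rs909788	0.097106
rs17603856	rs6459480	0.053081
rs17603856	rs9297016	0.13948
rs17603856	rs7772172	0.107363
rs17603856	rs6459472	0.089031
rs17603856	rs9367926	0.085468
rs17603856	rs6915310	0.115197
rs17603856	rs2237199	0.084703
rs17603856	rs7770062	0.100758
rs17603856	rs73366713	0.087094
rs17603856	rs3819405	0.05552
rs909788	rs6459480	0.775041
rs909788	rs9297016	0.834096
rs909788	rs7772172	0.831815
rs909788	rs6459472	0.116733
rs909788	rs9367926	0.097059
rs909788	rs6915310	0.146984
rs909788	rs2237199	0.134026
rs909788	rs7770062	0.074507
rs909788	rs73366713	0.106755
rs909788	rs3819405	0.145595
rs6459480	rs9297016	0.828562
rs6459480	rs7772172	0.786935
rs6459480	rs6459472	0.096992
rs6459480	rs9367926	0.101783
rs6459480	rs6915310	0.140189
rs6459480	rs2237199	0.12143
rs6459480	rs7770062	0.089814
rs6459480	rs73366713	0.096204
rs6459480	rs3819405	0.059231
rs9297016	rs7772172	0.799203
rs9297016	rs6459472	0.072902
rs9297016	rs9367926	0.059313
rs9297016	rs6915310	0.059128
rs9297016	rs2237199	0.071583
rs9297016	rs7770062	0.119913
rs9297016	rs73366713	0.067918
rs9297016	rs3819405	0.106839
rs7772172	rs6459472	0.110262
rs7772172	rs9367926	0.146627
rs7772172	rs6915310	0.09582
rs7772172	rs2237199	0.127453
rs7772172	rs7770062	0.053489
rs7772172	rs73366713	0.114461
rs7772172	rs3819405	0.14803
rs6459472	rs9367926	0.054738
rs6459472	rs6915310	0.140765
rs6459472	rs2237199	0.065578
rs6459472	rs7770062	0.117525
rs6459472	rs73366713	0.052528
rs6459472	rs3819405	0.056147
rs9367926	rs6915310	0.76347
rs9367926	rs2237199	0.140132
rs9367926	rs7770062	0.128289
rs9367926	rs73366713	0.116179
rs9367926	rs3819405	0.114946
rs6915310	rs2237199	0.079376
rs6915310	rs7770062	0.102811
rs6915310	rs73366713	0.098187
rs6915310	rs3819405	0.145111
rs2237199	rs7770062	0.09542
rs2237199	rs73366713	0.124692
rs2237199	rs3819405	0.085865
rs7770062	rs73366713	0.842542
rs7770062	rs3819405	0.135237
rs73366713	rs3819405	0.149189
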