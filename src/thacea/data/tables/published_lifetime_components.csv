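group,inc_direct,inc_indirect,qaly_gained
<65,28067,125958,7.0
40-49,28905,218738,8.3
50-59,28128,136023,7.1
60-64,27564,65659,6.0
>=65,32323,10052,4.2
65-69,30147,28157,5.4
70-74,30162,5664,4.4
75+,35468,0,3.3
All,30365,63314,5.5
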