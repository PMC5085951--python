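band,gender,value
40-49,M,0.0005
40-49,F,0.0004
50-59,M,0.0008
50-59,F,0.0006
60-64,M,0.0012
60-64,F,0.0009
65-69,M,0.0018
65-69,F,0.0014
70-74,M,0.0030
70-74,F,0.0023
75+,M,0.0080
75+,F,0.0060
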