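band,weight
40-49,0.10
50-59,0.22
60-64,0.16
65-69,0.18
70-74,0.15
75+,0.19
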