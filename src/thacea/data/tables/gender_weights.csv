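band,frac_female
40-49,0.44
50-59,0.50
60-64,0.54
65-69,0.56
70-74,0.57
75+,0.62
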