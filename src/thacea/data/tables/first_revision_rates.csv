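timing,cause,band,gender,value
early,aseptic,40-49,M,0.0131
early,aseptic,50-59,M,0.0131
early,aseptic,60-64,M,0.0131
early,aseptic,65-69,M,0.0131
early,aseptic,70-74,M,0.0131
early,aseptic,75+,M,0.0131
early,aseptic,40-49,F,0.0113
early,aseptic,50-59,F,0.0113
early,aseptic,60-64,F,0.0113
early,aseptic,65-69,F,0.0113
early,aseptic,70-74,F,0.0113
early,aseptic,75+,F,0.0113
late,aseptic,40-49,M,0.0061
late,aseptic,50-59,M,0.0061
late,aseptic,60-64,M,0.0061
late,aseptic,65-69,M,0.0061
late,aseptic,70-74,M,0.0061
late,aseptic,75+,M,0.0061
late,aseptic,40-49,F,0.0063
late,aseptic,50-59,F,0.0063
late,aseptic,60-64,F,0.0063
late,aseptic,65-69,F,0.0063
late,aseptic,70-74,F,0.0063
late,aseptic,75+,F,0.0063
early,infection,40-49,M,0.0020
early,infection,50-59,M,0.0020
early,infection,60-64,M,0.0020
early,infection,65-69,M,0.0020
early,infection,70-74,M,0.0020
early,infection,75+,M,0.0020
early,infection,40-49,F,0.0017
early,infection,50-59,F,0.0017
early,infection,60-64,F,0.0017
early,infection,65-69,F,0.0017
early,infection,70-74,F,0.0017
early,infection,75+,F,0.0017
late,infection,40-49,M,0.0009
late,infection,50-59,M,0.0009
late,infection,60-64,M,0.0009
late,infection,65-69,M,0.0009
late,infection,70-74,M,0.0009
late,infection,75+,M,0.0009
late,infection,40-49,F,0.0009
late,infection,50-59,F,0.0009
late,infection,60-64,F,0.0009
late,infection,65-69,F,0.0009
late,infection,70-74,F,0.0009
late,infection,75+,F,0.0009
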