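model,parameter,value,note
bridges,W0,50.3691,
bridges,a,1572.4030,
bridges,k,0.0008,
bridges,m,1.9403,
janoschek,a,1622.7710,
janoschek,W0,50.3691,
janoschek,k,0.0008,
janoschek,m,1.9403,
logistic,a,1568.0100,
logistic,b,18.5560,
logistic,k,0.0926,
gompertz,a,1718.5880,
gompertz,b,4.0519,
gompertz,k,0.0533,
von_bertalanffy,a,1840.0630,
von_bertalanffy,b,0.8455,
von_bertalanffy,k,0.0402,
richards,a,1666.3600,
richards,b,1.2669,sign ambiguous in source transcription; stored positive
richards,k,0.0622,
richards,m,0.2246,
schumacher,a,46.2627,
schumacher,b,24.1314,
schumacher,k,0.3990,
morgan,a,215425.0000,
morgan,b,102.7760,
morgan,k,2.5069,
sinusoidal,y0,762.8032,
sinusoidal,a,772.1740,
sinusoidal,b,150.8056,
sinusoidal,c,5.0027,
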