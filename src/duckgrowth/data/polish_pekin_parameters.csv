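model,parameter,value,note
bridges,W0,66.2416,
bridges,a,2226.5940,
bridges,k,0.0010,
bridges,m,1.9495,
janoschek,a,2292.8320,
janoschek,W0,66.2431,
janoschek,k,0.0010,
janoschek,m,1.9495,
logistic,a,2110.7400,
logistic,b,20.7380,
logistic,k,0.1144,
gompertz,a,2485.1810,
gompertz,b,4.0690,
gompertz,k,0.0595,
von_bertalanffy,a,2869.9300,
von_bertalanffy,b,0.8204,
von_bertalanffy,k,0.0406,
richards,a,2371.4450,
richards,b,0.9274,sign ambiguous in source transcription; stored positive
richards,k,0.0692,
richards,m,0.1737,
schumacher,a,69.5656,
schumacher,b,22.5424,
schumacher,k,0.4229,
morgan,a,245558.7000,
morgan,b,85.8948,
morgan,k,2.5469,
sinusoidal,y0,1031.9913,
sinusoidal,a,998.0614,
sinusoidal,b,115.5238,
sinusoidal,c,4.8717,
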