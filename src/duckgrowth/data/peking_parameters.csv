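model,parameter,value,note
bridges,W0,51.8410,
bridges,a,6045.7650,
bridges,k,0.0010,
bridges,m,1.8233,
janoschek,a,6097.6090,
janoschek,W0,51.8416,
janoschek,k,0.0010,
janoschek,m,1.8233,
logistic,a,4183.0000,
logistic,b,27.3406,
logistic,k,0.1210,
gompertz,a,5647.2660,
gompertz,b,4.4248,
gompertz,k,0.0546,
von_bertalanffy,a,7691.3450,
von_bertalanffy,b,0.8460,
von_bertalanffy,k,0.0319,
richards,a,6899.5060,
richards,b,0.7187,
richards,k,0.0380,
richards,m,0.2454,sign ambiguous in source transcription; stored positive
schumacher,a,120.9637,
schumacher,b,24.9350,
schumacher,k,0.4018,
morgan,a,651940.5000,
morgan,b,97.6016,
morgan,k,2.6174,
sinusoidal,y0,2253.2977,
sinusoidal,a,2266.2669,
sinusoidal,b,126.6430,
sinusoidal,c,4.8444,
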