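model,r2adj,dw,rmse,aic,bic
bridges,0.9991,1.9527,16.5897,82.0932,60.2777
janoschek,0.9991,1.9527,16.5897,82.0932,60.2777
logistic,0.9970,0.8467,30.4244,93.7640,71.6459
gompertz,0.9988,1.9321,18.9329,84.2772,62.1591
von_bertalanffy,0.9970,1.3511,30.3482,93.7139,71.5958
richards,0.9990,2.0184,17.7253,83.4174,61.6019
schumacher,0.9985,1.5839,21.5065,86.8262,64.7081
morgan,0.9990,0.9077,17.6102,82.8285,60.7104
sinusoidal,0.9997,2.9006,9.2164,70.3372,48.5217
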