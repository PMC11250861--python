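model,r2adj,dw,rmse,aic,bic
bridges,0.9986,3.3071,27.7946,72.2879,55.9702
janoschek,0.9986,3.3071,27.7946,72.2879,55.9702
logistic,0.9970,1.6013,40.2314,77.9898,61.5926
gompertz,0.9990,3.2858,23.7455,69.5540,53.1567
von_bertalanffy,0.9977,2.2428,35.6220,76.0429,59.6457
richards,0.9989,3.4370,24.6361,70.3579,54.0402
schumacher,0.9985,2.7143,28.6788,72.5741,56.1769
morgan,0.9978,1.7400,34.7150,75.6302,59.2330
sinusoidal,0.9990,3.4166,23.3750,69.5170,53.1992
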