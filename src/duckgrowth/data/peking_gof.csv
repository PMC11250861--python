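model,r2adj,dw,rmse,aic,bic
bridges,0.9997,2.2583,25.3281,70.8011,54.4834
janoschek,0.9997,2.2583,25.3281,70.8011,54.4834
logistic,0.9969,1.1155,79.2005,88.8272,72.4300
gompertz,0.9996,1.9332,29.8841,73.2327,56.8355
von_bertalanffy,0.9997,2.2068,24.1347,69.8139,53.4167
richards,0.9997,2.4028,25.6328,70.9924,54.6747
schumacher,0.9997,2.3543,23.8667,69.6353,53.2381
morgan,0.9996,1.4225,28.3278,72.3770,55.9798
sinusoidal,0.9998,2.6607,20.1142,67.1132,50.7954
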