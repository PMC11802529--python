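drug,rate_percent
empagliflozin,1.74
liraglutide,0.48
candesartan,7.28
obeticholic acid,0.62
resmetirom,0.00
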