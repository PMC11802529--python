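drug,n_reports
empagliflozin,43095
liraglutide,59268
candesartan,22033
obeticholic acid,6047
resmetirom,124
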