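drug,term,level,metric,estimate,ci_low,ci_high
liraglutide,Gastrointestinal disorders,soc,ROR,4.629,4.517,4.744
liraglutide,Gastrointestinal disorders,soc,PRR,3.566,3.492,3.642
liraglutide,Nausea,pt,ROR,5.853,5.604,6.114
liraglutide,Nausea,pt,PRR,5.392,5.169,5.624
liraglutide,Vomiting,pt,ROR,4.738,4.465,5.027
liraglutide,Vomiting,pt,PRR,4.572,4.313,4.847
liraglutide,Diarrhoea,pt,ROR,3.174,3.009,3.348
liraglutide,Diarrhoea,pt,PRR,3.087,2.929,3.252
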