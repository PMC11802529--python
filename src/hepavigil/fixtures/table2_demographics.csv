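drug,axis,level,count
empagliflozin,sex,female,18339
empagliflozin,sex,male,20798
empagliflozin,sex,unknown,3958
empagliflozin,age_group,<18,89
empagliflozin,age_group,18-44,1880
empagliflozin,age_group,45-64,10652
empagliflozin,age_group,65-74,8223
empagliflozin,age_group,>75,5450
empagliflozin,age_group,unknown,16801
empagliflozin,year,Before 2019,8109
empagliflozin,year,2019,5515
empagliflozin,year,2020,3743
empagliflozin,year,2021,4294
empagliflozin,year,2022,5780
empagliflozin,year,2023,7697
empagliflozin,region,Africa,155
empagliflozin,region,Americas,21904
empagliflozin,region,Asia,4703
empagliflozin,region,Europe,15273
empagliflozin,region,Oceania,1060
liraglutide,sex,female,40588
liraglutide,sex,male,16170
liraglutide,sex,unknown,2510
liraglutide,age_group,<18,394
liraglutide,age_group,18-44,9404
liraglutide,age_group,45-64,19396
liraglutide,age_group,65-74,7180
liraglutide,age_group,>75,1958
liraglutide,age_group,unknown,20936
liraglutide,year,Before 2019,28377
liraglutide,year,2019,4130
liraglutide,year,2020,3363
liraglutide,year,2021,4046
liraglutide,year,2022,5760
liraglutide,year,2023,8184
liraglutide,region,Africa,829
liraglutide,region,Americas,38248
liraglutide,region,Asia,7311
liraglutide,region,Europe,12272
liraglutide,region,Oceania,608
candesartan,sex,female,12512
candesartan,sex,male,8707
candesartan,sex,unknown,814
candesartan,age_group,<18,166
candesartan,age_group,18-44,1400
candesartan,age_group,45-64,5797
candesartan,age_group,65-74,4574
candesartan,age_group,>75,4745
candesartan,age_group,unknown,5351
candesartan,year,Before 2019,13679
candesartan,year,2019,2105
candesartan,year,2020,1832
candesartan,year,2021,1144
candesartan,year,2022,802
candesartan,year,2023,1234
candesartan,region,Africa,173
candesartan,region,Americas,4570
candesartan,region,Asia,4426
candesartan,region,Europe,12088
candesartan,region,Oceania,776
obeticholic acid,sex,female,3114
obeticholic acid,sex,male,352
obeticholic acid,sex,unknown,2581
obeticholic acid,age_group,<18,5
obeticholic acid,age_group,18-44,171
obeticholic acid,age_group,45-64,1051
obeticholic acid,age_group,65-74,579
obeticholic acid,age_group,>75,246
obeticholic acid,age_group,unknown,3995
obeticholic acid,year,Before 2019,2433
obeticholic acid,year,2019,1407
obeticholic acid,year,2020,656
obeticholic acid,year,2021,607
obeticholic acid,year,2022,335
obeticholic acid,year,2023,291
obeticholic acid,region,Africa,10
obeticholic acid,region,Americas,5118
obeticholic acid,region,Asia,8
obeticholic acid,region,Europe,906
obeticholic acid,region,Oceania,5
resmetirom,sex,female,1
resmetirom,sex,male,3
resmetirom,sex,unknown,120
resmetirom,age_group,<18,0
resmetirom,age_group,18-44,1
resmetirom,age_group,45-64,1
resmetirom,age_group,65-74,2
resmetirom,age_group,>75,0
resmetirom,age_group,unknown,120
resmetirom,region,Africa,0
resmetirom,region,Americas,124
resmetirom,region,Asia,0
resmetirom,region,Europe,0
resmetirom,region,Oceania,0
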