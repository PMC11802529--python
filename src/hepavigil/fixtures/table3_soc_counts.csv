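drug,soc,count
empagliflozin,Blood and lymphatic system disorders,264
empagliflozin,Cardiac disorders,1994
empagliflozin,"Congenital, familial and genetic disorders",203
empagliflozin,Ear and labyrinth disorders,423
empagliflozin,Endocrine disorders,72
empagliflozin,Eye disorders,823
empagliflozin,Gastrointestinal disorders,5291
empagliflozin,General disorders and administration site conditions,6655
empagliflozin,Hepatobiliary disorders,296
empagliflozin,Immune system disorders,285
empagliflozin,Infections and infestations,9846
empagliflozin,"Injury, poisoning and procedural complications",3024
empagliflozin,Investigations,7474
empagliflozin,Metabolism and nutrition disorders,8335
empagliflozin,Musculoskeletal and connective tissue disorders,1652
empagliflozin,"Neoplasms benign, malignant and unspecified (incl cysts and polyps)",640
empagliflozin,Nervous system disorders,4625
empagliflozin,"Pregnancy, puerperium and perinatal conditions",9
empagliflozin,Product issues,109
empagliflozin,Psychiatric disorders,1213
empagliflozin,Renal and urinary disorders,4904
empagliflozin,Reproductive system and breast disorders,2997
empagliflozin,"Respiratory, thoracic and mediastinal disorders",1525
empagliflozin,Skin and subcutaneous tissue disorders,4116
empagliflozin,Social circumstances,165
empagliflozin,Surgical and medical procedures,1106
empagliflozin,Vascular disorders,1253
liraglutide,Blood and lymphatic system disorders,275
liraglutide,Cardiac disorders,1369
liraglutide,"Congenital, familial and genetic disorders",58
liraglutide,Ear and labyrinth disorders,320
liraglutide,Endocrine disorders,369
liraglutide,Eye disorders,1056
liraglutide,Gastrointestinal disorders,28252
liraglutide,General disorders and administration site conditions,17359
liraglutide,Hepatobiliary disorders,1189
liraglutide,Immune system disorders,670
liraglutide,Infections and infestations,2155
liraglutide,"Injury, poisoning and procedural complications",0
liraglutide,Investigations,9816
liraglutide,Metabolism and nutrition disorders,7104
liraglutide,Musculoskeletal and connective tissue disorders,2251
liraglutide,"Neoplasms benign, malignant and unspecified (incl cysts and polyps)",2184
liraglutide,Nervous system disorders,8282
liraglutide,"Pregnancy, puerperium and perinatal conditions",135
liraglutide,Product issues,1277
liraglutide,Psychiatric disorders,2736
liraglutide,Renal and urinary disorders,1443
liraglutide,Reproductive system and breast disorders,702
liraglutide,"Respiratory, thoracic and mediastinal disorders",1630
liraglutide,Skin and subcutaneous tissue disorders,3921
liraglutide,Social circumstances,147
liraglutide,Surgical and medical procedures,860
liraglutide,Vascular disorders,991
candesartan,Blood and lymphatic system disorders,408
candesartan,Cardiac disorders,1488
candesartan,"Congenital, familial and genetic disorders",150
candesartan,Ear and labyrinth disorders,550
candesartan,Endocrine disorders,94
candesartan,Eye disorders,783
candesartan,Gastrointestinal disorders,3524
candesartan,General disorders and administration site conditions,5449
candesartan,Hepatobiliary disorders,401
candesartan,Immune system disorders,385
candesartan,Infections and infestations,893
candesartan,"Injury, poisoning and procedural complications",1976
candesartan,Investigations,2506
candesartan,Metabolism and nutrition disorders,1762
candesartan,Musculoskeletal and connective tissue disorders,2372
candesartan,"Neoplasms benign, malignant and unspecified (incl cysts and polyps)",245
candesartan,Nervous system disorders,5110
candesartan,"Pregnancy, puerperium and perinatal conditions",157
candesartan,Product issues,838
candesartan,Psychiatric disorders,1404
candesartan,Renal and urinary disorders,1735
candesartan,Reproductive system and breast disorders,330
candesartan,"Respiratory, thoracic and mediastinal disorders",2724
candesartan,Skin and subcutaneous tissue disorders,3424
candesartan,Social circumstances,101
candesartan,Surgical and medical procedures,142
candesartan,Vascular disorders,2434
obeticholic acid,Blood and lymphatic system disorders,108
obeticholic acid,Cardiac disorders,167
obeticholic acid,"Congenital, familial and genetic disorders",8
obeticholic acid,Ear and labyrinth disorders,52
obeticholic acid,Endocrine disorders,25
obeticholic acid,Eye disorders,116
obeticholic acid,Gastrointestinal disorders,1315
obeticholic acid,General disorders and administration site conditions,1987
obeticholic acid,Hepatobiliary disorders,519
obeticholic acid,Immune system disorders,113
obeticholic acid,Infections and infestations,433
obeticholic acid,"Injury, poisoning and procedural complications",846
obeticholic acid,Investigations,948
obeticholic acid,Metabolism and nutrition disorders,239
obeticholic acid,Musculoskeletal and connective tissue disorders,564
obeticholic acid,"Neoplasms benign, malignant and unspecified (incl cysts and polyps)",125
obeticholic acid,Nervous system disorders,789
obeticholic acid,"Pregnancy, puerperium and perinatal conditions",3
obeticholic acid,Product issues,20
obeticholic acid,Psychiatric disorders,413
obeticholic acid,Renal and urinary disorders,204
obeticholic acid,Reproductive system and breast disorders,33
obeticholic acid,"Respiratory, thoracic and mediastinal disorders",312
obeticholic acid,Skin and subcutaneous tissue disorders,2743
obeticholic acid,Social circumstances,101
obeticholic acid,Surgical and medical procedures,790
obeticholic acid,Vascular disorders,198
resmetirom,Blood and lymphatic system disorders,1
resmetirom,Cardiac disorders,1
resmetirom,"Congenital, familial and genetic disorders",0
resmetirom,Ear and labyrinth disorders,1
resmetirom,Endocrine disorders,0
resmetirom,Eye disorders,1
resmetirom,Gastrointestinal disorders,61
resmetirom,General disorders and administration site conditions,37
resmetirom,Hepatobiliary disorders,9
resmetirom,Immune system disorders,3
resmetirom,Infections and infestations,9
resmetirom,"Injury, poisoning and procedural complications",16
resmetirom,Investigations,50
resmetirom,Metabolism and nutrition disorders,5
resmetirom,Musculoskeletal and connective tissue disorders,5
resmetirom,"Neoplasms benign, malignant and unspecified (incl cysts and polyps)",1
resmetirom,Nervous system disorders,25
resmetirom,"Pregnancy, puerperium and perinatal conditions",0
resmetirom,Product issues,0
resmetirom,Psychiatric disorders,5
resmetirom,Renal and urinary disorders,4
resmetirom,Reproductive system and breast disorders,1
resmetirom,"Respiratory, thoracic and mediastinal disorders",2
resmetirom,Skin and subcutaneous tissue disorders,22
resmetirom,Social circumstances,2
resmetirom,Surgical and medical procedures,0
resmetirom,Vascular disorders,1
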