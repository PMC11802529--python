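drug,pt,rate_percent
empagliflozin,Diabetic ketoacidosis,6.67
empagliflozin,Urinary tract infection,5.26
empagliflozin,Fungal infection,4.89
empagliflozin,Weight decreased,4.52
empagliflozin,Blood glucose increased,3.89
empagliflozin,Dizziness,3.61
empagliflozin,Pollakiuria,3.18
empagliflozin,Nausea,2.93
empagliflozin,Euglycaemic diabetic ketoacidosis,2.88
empagliflozin,Rash,2.79
empagliflozin,Ketoacidosis,2.78
empagliflozin,Pruritus,2.71
empagliflozin,Diarrhoea,2.39
empagliflozin,Vomiting,2.13
empagliflozin,Balanoposthitis,2.09
empagliflozin,Fatigue,1.88
empagliflozin,Glycosylated haemoglobin increased,1.68
empagliflozin,Dehydration,1.66
empagliflozin,Malaise,1.63
empagliflozin,Death,1.59
liraglutide,Nausea,20.84
liraglutide,Vomiting,9.96
liraglutide,Diarrhoea,8.85
liraglutide,Blood glucose increased,5.95
liraglutide,Headache,5.67
liraglutide,Constipation,5.18
liraglutide,Pancreatitis,4.45
liraglutide,Decreased appetite,4.20
liraglutide,Dizziness,4.12
liraglutide,Abdominal pain upper,3.72
liraglutide,Fatigue,3.62
liraglutide,Dyspepsia,3.12
liraglutide,Weight decreased,3.02
liraglutide,Abdominal pain,2.77
liraglutide,Injection site erythema,2.69
liraglutide,Injection site pruritus,2.65
liraglutide,Abdominal discomfort,2.51
liraglutide,Weight loss poor,2.51
liraglutide,Malaise,2.45
liraglutide,Eructation,2.44
candesartan,Dizziness,4.70
candesartan,Headache,3.30
candesartan,Cough,2.46
candesartan,Nausea,2.20
candesartan,Pruritus,2.12
candesartan,Hypotension,1.82
candesartan,Fatigue,1.82
candesartan,Dyspnoea,1.78
candesartan,Myalgia,1.58
candesartan,Product substitution issue,1.55
candesartan,Acute kidney injury,1.52
candesartan,Blood pressure increased,1.49
candesartan,Rash,1.46
candesartan,Diarrhoea,1.45
candesartan,Hypertension,1.42
candesartan,Arthralgia,1.41
candesartan,Malaise,1.39
candesartan,Hyperkalaemia,1.34
candesartan,Palpitations,1.05
candesartan,Angioedema,1.03
obeticholic acid,Pruritus,40.04
obeticholic acid,Fatigue,12.01
obeticholic acid,Product dose omission issue,5.84
obeticholic acid,Nausea,4.66
obeticholic acid,Drug ineffective,4.18
obeticholic acid,Arthralgia,4.18
obeticholic acid,Rash,4.02
obeticholic acid,Constipation,3.64
obeticholic acid,Dizziness,3.54
obeticholic acid,Therapy interrupted,3.27
obeticholic acid,Diarrhoea,3.22
obeticholic acid,Hospitalisation,3.19
obeticholic acid,Blood alkaline phosphatase increased,2.84
obeticholic acid,Abdominal pain upper,2.83
obeticholic acid,Malaise,2.61
obeticholic acid,Headache,2.45
obeticholic acid,Insomnia,2.13
obeticholic acid,Abdominal distension,2.07
obeticholic acid,Vomiting,2.02
obeticholic acid,Abdominal pain,1.98
resmetirom,Nausea,20.97
resmetirom,Alanine aminotransferase increased,16.13
resmetirom,Aspartate aminotransferase increased,16.13
resmetirom,Diarrhoea,12.90
resmetirom,Fatigue,12.90
resmetirom,Dizziness,12.90
resmetirom,Pruritus,12.90
resmetirom,Hepatic enzyme increased,11.29
resmetirom,Abdominal pain upper,8.87
resmetirom,Vomiting,5.65
resmetirom,Blood bilirubin increased,5.65
resmetirom,Rash,5.65
resmetirom,Abdominal pain,4.84
resmetirom,Abdominal discomfort,4.03
resmetirom,Blood glucose increased,4.03
resmetirom,Flatulence,3.23
resmetirom,Blood alkaline phosphatase increased,3.23
resmetirom,Back pain,3.23
resmetirom,Headache,3.23
resmetirom,Syncope,3.23
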