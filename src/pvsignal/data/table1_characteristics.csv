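section,stratum,stiripentol,cannabidiol,fenfluramine
age_group,Not Specified,226,581,216
age_group,0–1 Month,0,2,2
age_group,2 Months–2 Years,94,157,28
age_group,3–11 Years,262,991,130
age_group,12–17 Years,113,661,92
age_group,18–64 Years,126,1732,356
age_group,65–85 Years,1,93,27
age_group,More than 85 Years,0,5,1
sex,Female,383,1948,506
sex,Male,423,2149,243
sex,Not Specified,16,125,103
reporter_group,Healthcare Professional,444,3974,692
reporter_group,Non-Healthcare Professional,378,248,121
reporter_group,Not Specified,0,0,39
region,EEA,229,865,340
region,Non-EEA,593,3357,512
country,FR,66,416,94
country,DE,57,116,132
country,GB,16,101,0
country,IT,28,64,24
country,ES,30,50,17
country,NL,0,32,0
country,AT,0,15,0
country,Others,32,71,61
seriousness,Non-Serious,93,603,137
seriousness,Serious,728,3619,713
seriousness,Not Specified,1,0,2
outcome,Fatal,42,503,67
outcome,Not Recovered/Not Resolved,138,1169,278
outcome,Not Specified,0,0,37
outcome,Recovered/Resolved,300,1423,320
outcome,Recovered/Resolved with Sequelae,6,16,19
outcome,Recovering/Resolving,134,455,93
outcome,Unknown,1600,5257,1267
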