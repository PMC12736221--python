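soc,stiripentol,cannabidiol,fenfluramine
"Blood and lymphatic system disorders",26,47,15
"Cardiac disorders",2,85,269
"Congenital, familial, and genetic disorders",1,13,8
"Ear and labyrinth disorders",1,24,5
"Endocrine disorders",3,12,4
"Eye disorders",5,59,11
"Gastrointestinal disorders",103,550,76
"General disorders and administration site conditions",313,1200,234
"Hepatobiliary disorders",15,61,15
"Immune system disorders",5,50,6
"Infections and infestations",117,551,83
"Injury, poisoning, and procedural complications",435,1232,140
"Investigations",105,428,112
"Metabolism and nutritional disorders",127,207,97
"Musculoskeletal and connective tissue disorders",27,80,20
"Neoplasms: benign, malignant, and unspecified",1,26,7
"Nervous system disorders",563,2292,368
"Pregnancy, puerperium, and perinatal conditions",1,10,3
"Product issues",6,203,8
"Psychiatric disorders",117,566,109
"Renal and urinary disorders",16,68,19
"Reproductive system and breast disorders",2,16,7
"Respiratory, thoracic, and mediastinal disorders",26,249,181
"Skin and subcutaneous tissue disorders",32,151,22
"Social circumstances",3,49,5
"Surgical and medical procedures",60,173,36
"Vascular disorders",4,70,62
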