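pt	soc
Anaemia	Blood and lymphatic system disorders
Neutropenia	Blood and lymphatic system disorders
Thrombocytopenia	Blood and lymphatic system disorders
Aortic valve incompetence	Cardiac disorders
Bradycardia	Cardiac disorders
Cardiac failure	Cardiac disorders
Cardiac failure congestive	Cardiac disorders
Cardiac valve disease	Cardiac disorders
Cardiovascular disorder	Cardiac disorders
Left atrial dilatation	Cardiac disorders
Left ventricular hypertrophy	Cardiac disorders
Mitral valve incompetence	Cardiac disorders
Mitral valve stenosis	Cardiac disorders
Palpitations	Cardiac disorders
Right ventricular failure	Cardiac disorders
Tachycardia	Cardiac disorders
Tricuspid valve incompetence	Cardiac disorders
Atrial septal defect	Congenital, familial, and genetic disorders
Cleft palate	Congenital, familial, and genetic disorders
Congenital brain malformation	Congenital, familial, and genetic disorders
Tinnitus	Ear and labyrinth disorders
Vertigo	Ear and labyrinth disorders
Adrenal insufficiency	Endocrine disorders
Hypothyroidism	Endocrine disorders
Diplopia	Eye disorders
Eyelid ptosis	Eye disorders
Vision blurred	Eye disorders
Abdominal pain	Gastrointestinal disorders
Constipation	Gastrointestinal disorders
Diarrhoea	Gastrointestinal disorders
Nausea	Gastrointestinal disorders
Vomiting	Gastrointestinal disorders
Condition aggravated	General disorders and administration site conditions
Drug ineffective	General disorders and administration site conditions
Fatigue	General disorders and administration site conditions
Irritability	General disorders and administration site conditions
Pyrexia	General disorders and administration site conditions
Hepatic enzyme increased mixed	Hepatobiliary disorders
Hepatitis	Hepatobiliary disorders
Hepatotoxicity	Hepatobiliary disorders
Anaphylactic reaction	Immune system disorders
Hypersensitivity	Immune system disorders
Nasopharyngitis	Infections and infestations
Pneumonia	Infections and infestations
Urinary tract infection	Infections and infestations
Fall	Injury, poisoning, and procedural complications
Inappropriate schedule of product administration	Injury, poisoning, and procedural complications
Off label use	Injury, poisoning, and procedural complications
Overdose	Injury, poisoning, and procedural complications
Product dose omission issue	Injury, poisoning, and procedural complications
Product preparation issue	Injury, poisoning, and procedural complications
Product use in unapproved indication	Injury, poisoning, and procedural complications
Product use issue	Injury, poisoning, and procedural complications
Wrong technique in product usage process	Injury, poisoning, and procedural complications
Alanine aminotransferase increased	Investigations
Echocardiogram abnormal	Investigations
Weight decreased	Investigations
Decreased appetite	Metabolism and nutritional disorders
Dehydration	Metabolism and nutritional disorders
Hyperammonaemia	Metabolism and nutritional disorders
Arthralgia	Musculoskeletal and connective tissue disorders
Muscular weakness	Musculoskeletal and connective tissue disorders
Myalgia	Musculoskeletal and connective tissue disorders
Lymphoma	Neoplasms: benign, malignant, and unspecified
Neoplasm malignant	Neoplasms: benign, malignant, and unspecified
Amnesia	Nervous system disorders
Ataxia	Nervous system disorders
Atonic seizures	Nervous system disorders
Balance disorder	Nervous system disorders
Cognitive disorder	Nervous system disorders
Coma	Nervous system disorders
Depressed level of consciousness	Nervous system disorders
Disturbance in attention	Nervous system disorders
Dizziness	Nervous system disorders
Drooling	Nervous system disorders
Dysarthria	Nervous system disorders
Dyskinesia	Nervous system disorders
Epilepsy	Nervous system disorders
Generalized tonic–clonic seizure	Nervous system disorders
Headache	Nervous system disorders
Hypersomnia	Nervous system disorders
Hypotonia	Nervous system disorders
Lethargy	Nervous system disorders
Loss of consciousness	Nervous system disorders
Memory impairment	Nervous system disorders
Myoclonic epilepsy	Nervous system disorders
Partial seizures	Nervous system disorders
Petit mal epilepsy	Nervous system disorders
Psychomotor hyperactivity	Nervous system disorders
Sedation	Nervous system disorders
Seizure	Nervous system disorders
Seizure cluster	Nervous system disorders
Somnolence	Nervous system disorders
Speech disorder	Nervous system disorders
Status epilepticus	Nervous system disorders
Syncope	Nervous system disorders
Tonic convulsion	Nervous system disorders
Tremor	Nervous system disorders
Abortion spontaneous	Pregnancy, puerperium, and perinatal conditions
Premature baby	Pregnancy, puerperium, and perinatal conditions
Liquid product physical issue	Product issues
Product container issue	Product issues
Product distribution issue	Product issues
Product quality issue	Product issues
Product supply issue	Product issues
Aggression	Psychiatric disorders
Agitation	Psychiatric disorders
Insomnia	Psychiatric disorders
Acute kidney injury	Renal and urinary disorders
Urinary retention	Renal and urinary disorders
Amenorrhoea	Reproductive system and breast disorders
Gynaecomastia	Reproductive system and breast disorders
Cough	Respiratory, thoracic, and mediastinal disorders
Dyspnoea	Respiratory, thoracic, and mediastinal disorders
Pulmonary arterial hypertension	Respiratory, thoracic, and mediastinal disorders
Pulmonary hypertension	Respiratory, thoracic, and mediastinal disorders
Alopecia	Skin and subcutaneous tissue disorders
Pruritus	Skin and subcutaneous tissue disorders
Rash	Skin and subcutaneous tissue disorders
Loss of personal independence in daily activities	Social circumstances
Treatment noncompliance	Social circumstances
Hospitalisation	Surgical and medical procedures
Therapy interrupted	Surgical and medical procedures
Circulatory collapse	Vascular disorders
Hypertension	Vascular disorders
Hypotension	Vascular disorders
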