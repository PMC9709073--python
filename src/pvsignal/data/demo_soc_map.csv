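pt,soc
Nausea,Gastrointestinal disorders
Diarrhoea,Gastrointestinal disorders
Vomiting,Gastrointestinal disorders
Abdominal pain,Gastrointestinal disorders
Constipation,Gastrointestinal disorders
Fatigue,General disorders and administration site conditions
Asthenia,General disorders and administration site conditions
Malaise,General disorders and administration site conditions
Drug ineffective,General disorders and administration site conditions
Headache,Nervous system disorders
Dizziness,Nervous system disorders
Dysgeusia,Nervous system disorders
Neuropathy peripheral,Nervous system disorders
Insomnia,Psychiatric disorders
Anxiety,Psychiatric disorders
Dyspnoea,"Respiratory, thoracic and mediastinal disorders"
Cough,"Respiratory, thoracic and mediastinal disorders"
Arthralgia,Musculoskeletal and connective tissue disorders
Back pain,Musculoskeletal and connective tissue disorders
Hypertension,Vascular disorders
Hot flush,Vascular disorders
Decreased appetite,Metabolism and nutrition disorders
Dehydration,Metabolism and nutrition disorders
Anaemia,Blood and lymphatic system disorders
Thrombocytopenia,Blood and lymphatic system disorders
Weight decreased,Investigations
Blood pressure increased,Investigations
Haemoglobin decreased,Investigations
White blood cell count decreased,Investigations
Platelet count decreased,Investigations
Urinary tract infection,Infections and infestations
Photosensitivity reaction,Skin and subcutaneous tissue disorders
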