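level,soc,term,a,ror,ror_low,ror_high,prr,chi2,ic,ic025,ebgm,ebgm05,ror_sig,prr_sig,ic_sig,ebgm_sig,all_four,expected
pt,Gastrointestinal disorders,Nausea,53,18.52,8.67,39.54,4.23,71.21,1.05,0.66,2.06,1.09,True,True,True,False,False,True
pt,Blood and lymphatic system disorders,Thrombocytopenia,20,59.56,7.77,456.46,41.54,42.10,1.55,0.92,2.93,0.53,True,True,True,False,False,True
pt,Nervous system disorders,Headache,18,1.28,0.65,2.52,1.21,0.53,0.18,-0.27,1.13,0.64,False,False,False,False,False,True
pt,General disorders and administration site conditions,Fatigue,14,1.00,0.49,2.06,1.00,0.00,0.00,-0.55,1.00,0.55,False,False,False,False,False,True
pt,Gastrointestinal disorders,Vomiting,12,1.47,0.66,3.27,1.38,0.90,0.30,-0.26,1.23,0.63,False,False,False,False,False,True
pt,General disorders and administration site conditions,Asthenia,10,1.45,0.61,3.44,1.38,0.73,0.30,-0.33,1.23,0.60,False,False,False,False,False,True
pt,Metabolism and nutrition disorders,Decreased appetite,10,1.45,0.61,3.44,1.38,0.73,0.30,-0.33,1.23,0.60,False,False,False,False,False,True
pt,Nervous system disorders,Dizziness,10,0.93,0.41,2.11,0.94,0.03,-0.06,-0.74,0.96,0.49,False,False,False,False,False,True
pt,Psychiatric disorders,Insomnia,10,1.86,0.76,4.57,1.73,1.89,0.48,-0.11,1.40,0.66,False,False,False,False,False,True
pt,Gastrointestinal disorders,Abdominal pain,9,1.12,0.47,2.66,1.10,0.06,0.09,-0.61,1.07,0.51,False,False,False,False,False,True
pt,Musculoskeletal and connective tissue disorders,Arthralgia,8,0.62,0.26,1.46,0.66,1.23,-0.42,-1.24,0.75,0.36,False,False,False,False,False,True
pt,Skin and subcutaneous tissue disorders,Photosensitivity reaction,8,6.18,1.58,24.13,5.54,8.59,1.16,0.73,2.24,0.71,True,True,True,False,False,False
pt,Psychiatric disorders,Anxiety,7,1.13,0.43,2.99,1.12,0.06,0.11,-0.71,1.08,0.48,False,False,False,False,False,True
pt,"Respiratory, thoracic and mediastinal disorders",Cough,7,0.97,0.37,2.50,0.97,0.01,-0.03,-0.86,0.98,0.44,False,False,False,False,False,True
pt,General disorders and administration site conditions,Malaise,7,1.92,0.66,5.54,1.82,1.48,0.52,-0.20,1.44,0.59,False,False,False,False,False,True
pt,Investigations,Weight decreased,7,1.24,0.46,3.31,1.21,0.18,0.18,-0.62,1.13,0.50,False,False,False,False,False,True
pt,Musculoskeletal and connective tissue disorders,Back pain,6,0.88,0.32,2.40,0.89,0.06,-0.12,-1.04,0.92,0.40,False,False,False,False,False,True
pt,Gastrointestinal disorders,Diarrhoea,6,0.45,0.17,1.15,0.50,2.89,-0.75,-1.74,0.60,0.27,False,False,False,False,False,True
pt,Vascular disorders,Hypertension,6,0.62,0.24,1.64,0.66,0.94,-0.44,-1.40,0.74,0.33,False,False,False,False,False,True
pt,Blood and lymphatic system disorders,Anaemia,5,0.54,0.19,1.53,0.58,1.37,-0.58,-1.66,0.67,0.28,False,False,False,False,False,True
pt,Metabolism and nutrition disorders,Dehydration,4,0.82,0.25,2.72,0.83,0.11,-0.19,-1.35,0.88,0.32,False,False,False,False,False,True
pt,"Respiratory, thoracic and mediastinal disorders",Dyspnoea,4,0.30,0.10,0.91,0.35,4.92,-1.19,-2.46,0.44,0.17,False,False,False,False,False,True
pt,Investigations,Platelet count decreased,3,1.26,0.29,5.43,1.25,0.09,0.21,-1.05,1.15,0.34,False,False,False,False,False,True
pt,Infections and infestations,Urinary tract infection,3,0.68,0.18,2.59,0.69,0.33,-0.38,-1.76,0.77,0.25,False,False,False,False,False,True
pt,Investigations,Haemoglobin decreased,2,0.83,0.16,4.37,0.83,0.05,-0.19,-1.85,0.88,0.22,False,False,False,False,False,True
pt,Nervous system disorders,Neuropathy peripheral,2,2.11,0.29,15.33,2.08,0.57,0.62,-0.76,1.54,0.29,False,False,False,False,False,False
pt,General disorders and administration site conditions,Drug ineffective,1,0.41,0.05,3.55,0.42,0.71,-0.96,-3.53,0.51,0.08,False,False,False,False,False,False
pt,Vascular disorders,Hot flush,1,0.51,0.06,4.67,0.52,0.37,-0.70,-3.21,0.62,0.10,False,False,False,False,False,True
pt,Investigations,White blood cell count decreased,1,0.51,0.06,4.67,0.52,0.37,-0.70,-3.21,0.62,0.10,False,False,False,False,False,True
pt,Investigations,Blood pressure increased,0,,,,0.00,4.01,,,,,False,False,False,False,False,False
pt,Nervous system disorders,Dysgeusia,0,,,,0.00,2.98,,,,,False,False,False,False,False,True
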