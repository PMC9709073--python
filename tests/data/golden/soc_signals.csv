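level,soc,term,a,ror,ror_low,ror_high,prr,chi2,ic,ic025,ebgm,ebgm05,ror_sig,prr_sig,ic_sig,ebgm_sig,all_four,expected
soc,Gastrointestinal disorders,Gastrointestinal disorders,57,7.90,3.50,17.83,1.85,29.80,0.54,0.16,1.45,0.73,True,False,True,False,False,False
soc,General disorders and administration site conditions,General disorders and administration site conditions,29,1.17,0.64,2.13,1.10,0.27,0.09,-0.23,1.06,0.64,False,False,False,False,False,False
soc,Nervous system disorders,Nervous system disorders,28,1.29,0.70,2.35,1.16,0.67,0.14,-0.17,1.10,0.67,False,False,False,False,False,False
soc,Blood and lymphatic system disorders,Blood and lymphatic system disorders,24,3.57,1.78,7.19,2.62,13.57,0.78,0.53,1.72,0.95,True,True,True,False,False,False
soc,Psychiatric disorders,Psychiatric disorders,16,1.59,0.77,3.27,1.44,1.61,0.34,-0.12,1.26,0.69,False,False,False,False,False,False
soc,Musculoskeletal and connective tissue disorders,Musculoskeletal and connective tissue disorders,14,0.82,0.40,1.65,0.86,0.32,-0.16,-0.72,0.90,0.50,False,False,False,False,False,False
soc,Metabolism and nutrition disorders,Metabolism and nutrition disorders,13,1.22,0.57,2.59,1.17,0.26,0.15,-0.40,1.11,0.59,False,False,False,False,False,False
soc,Investigations,Investigations,12,0.73,0.35,1.53,0.78,0.70,-0.25,-0.89,0.84,0.45,False,False,False,False,False,False
soc,"Respiratory, thoracic and mediastinal disorders","Respiratory, thoracic and mediastinal disorders",11,0.52,0.25,1.10,0.60,2.99,-0.53,-1.23,0.69,0.37,False,False,False,False,False,False
soc,Skin and subcutaneous tissue disorders,Skin and subcutaneous tissue disorders,8,6.18,1.58,24.13,5.54,8.59,1.16,0.73,2.24,0.71,True,True,True,False,False,False
soc,Vascular disorders,Vascular disorders,7,0.62,0.25,1.54,0.66,1.08,-0.43,-1.31,0.74,0.35,False,False,False,False,False,False
soc,Infections and infestations,Infections and infestations,3,0.68,0.18,2.59,0.69,0.33,-0.38,-1.76,0.77,0.25,False,False,False,False,False,False
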