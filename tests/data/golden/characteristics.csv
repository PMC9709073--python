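category,level,count,percent
sex,Female,45,69.23
sex,Male,3,4.62
sex,Unknown,17,26.15
age,<40,1,1.54
age,40-50,0,0.0
age,>50,29,44.62
age,Unknown or missing,35,53.85
indication,Ovarian cancer,47,72.31
indication,Product used for unknown indication,14,21.54
indication,Malignant peritoneal neoplasm,2,3.08
indication,Fallopian tube cancer,2,3.08
serious_outcome,Death,4,6.15
serious_outcome,Disability,0,0.0
serious_outcome,Hospitalization-initial or prolonged,12,18.46
serious_outcome,Life-threatening,2,3.08
serious_outcome,Other serious medical events,26,40.0
serious_outcome,Other outcomes (CA/RI),0,0.0
country,US,54,83.08
country,DE,6,9.23
country,JP,3,4.62
country,GB,1,1.54
country,CA,1,1.54
occupation,Consumer,44,67.69
occupation,Physician,15,23.08
occupation,Pharmacist,0,0.0
occupation,Health professional,0,0.0
occupation,Lawyer,0,0.0
occupation,Other health-professional,5,7.69
occupation,Unknown,1,1.54
reporting_year,2017,16,24.62
reporting_year,2018,11,16.92
reporting_year,2019,13,20.0
reporting_year,2020,10,15.38
reporting_year,2021,15,23.08
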