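Fatigue
Nausea
Vomiting
Constipation
Anaemia
Thrombocytopenia
Headache
Hypertension
Insomnia
Diarrhoea
Abdominal pain
Dizziness
Decreased appetite
Asthenia
Platelet count decreased
White blood cell count decreased
Neutrophil count decreased
Haemoglobin decreased
Palpitations
Dysgeusia
Back pain
Arthralgia
Dyspnoea
Cough
Urinary tract infection
Weight decreased
Anxiety
Hot flush
Dehydration
Malaise
Dyspepsia
Stomatitis
Rash
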