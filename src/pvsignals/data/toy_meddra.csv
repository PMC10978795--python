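pt,soc,soc_code
Seizure,Nervous system disorders,10029205
Somnolence,Nervous system disorders,10029205
Dizziness,Nervous system disorders,10029205
Balance disorder,Nervous system disorders,10029205
Memory impairment,Nervous system disorders,10029205
Hypersomnia,Nervous system disorders,10029205
Lethargy,Nervous system disorders,10029205
Generalised tonic-clonic seizure,Nervous system disorders,10029205
Dysarthria,Nervous system disorders,10029205
Aura,Nervous system disorders,10029205
Disturbance in attention,Nervous system disorders,10029205
Amnesia,Nervous system disorders,10029205
Speech disorder,Nervous system disorders,10029205
Partial seizures,Nervous system disorders,10029205
Headache,Nervous system disorders,10029205
Tremor,Nervous system disorders,10029205
Product dose omission issue,"Injury, poisoning and procedural complications",10022117
Fall,"Injury, poisoning and procedural complications",10022117
Wrong technique in product usage process,"Injury, poisoning and procedural complications",10022117
Product use issue,"Injury, poisoning and procedural complications",10022117
Head banging,"Injury, poisoning and procedural complications",10022117
Fatigue,General disorders and administration site conditions,10018065
Feeling abnormal,General disorders and administration site conditions,10018065
Gait disturbance,General disorders and administration site conditions,10018065
Adverse event,General disorders and administration site conditions,10018065
Feeling drunk,General disorders and administration site conditions,10018065
Drug ineffective,General disorders and administration site conditions,10018065
Irritability,Psychiatric disorders,10037175
Anger,Psychiatric disorders,10037175
Abnormal behaviour,Psychiatric disorders,10037175
Insomnia,Psychiatric disorders,10037175
Anxiety,Psychiatric disorders,10037175
Vision blurred,Eye disorders,10015919
Diplopia,Eye disorders,10015919
Therapy interrupted,Surgical and medical procedures,10042613
Product availability issue,Product issues,10077536
Arthralgia,Musculoskeletal and connective tissue disorders,10028395
Myalgia,Musculoskeletal and connective tissue disorders,10028395
Weight decreased,Investigations,10022891
Blood pressure increased,Investigations,10022891
Cough,"Respiratory, thoracic and mediastinal disorders",10038738
Dyspnoea,"Respiratory, thoracic and mediastinal disorders",10038738
Nausea,Gastrointestinal disorders,10017947
Vomiting,Gastrointestinal disorders,10017947
Rash,Skin and subcutaneous tissue disorders,10040785
Pruritus,Skin and subcutaneous tissue disorders,10040785
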