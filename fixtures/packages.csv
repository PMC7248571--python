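id,name
1,Maternal and newborn health
2,Child health
3,School-age health and development
4,Adolescent health and development
5,Reproductive health and contraception
6,HIV and STIs
7,Tuberculosis
8,Malaria and adult febrile illness
9,Neglected tropical diseases
10,Pandemic and emergency preparedness
11,"Cardiovascular, respiratory, and related disorders"
12,Cancer
13,"Mental, neurological, and substance use disorders"
14,Musculoskeletal disorders
15,Congenital and genetic disorders
16,Injury prevention
17,Environmental improvement
18,Surgery
19,Rehabilitation
20,Palliative care and pain control
21,Pathology
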