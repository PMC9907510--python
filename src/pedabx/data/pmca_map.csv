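icd_prefix,icd_version,body_system
J45,10,pulmonary_respiratory
493,9,pulmonary_respiratory
H90,10,otologic
H91,10,otologic
389,9,otologic
D80,10,immunological
D84,10,immunological
279,9,immunological
N18,10,renal
585,9,renal
K50,10,gastrointestinal
K21,10,gastrointestinal
555,9,gastrointestinal
G40,10,neurological
345,9,neurological
N13,10,genitourinary
Q54,10,genitourinary
593,9,genitourinary
D56,10,hematological
D57,10,hematological
282,9,hematological
Q21,10,cardiac
I42,10,cardiac
745,9,cardiac
E10,10,endocrinological
250,9,endocrinological
E70,10,metabolic
270,9,metabolic
L20,10,dermatological
Q80,10,dermatological
691,9,dermatological
Q90,10,genetic
758,9,genetic
M08,10,musculoskeletal
714,9,musculoskeletal
Q35,10,craniofacial
Q37,10,craniofacial
749,9,craniofacial
H26,10,ophthalmological
Q12,10,ophthalmological
743,9,ophthalmological
F84,10,mental_health
299,9,mental_health
C91,10,malignancy
204,9,malignancy
J35,10,otolaryngological
474,9,otolaryngological
Q87,10,genetic
Q87,10,craniofacial
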