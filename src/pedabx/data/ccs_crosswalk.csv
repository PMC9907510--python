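icd_code,icd_version,ccs_code,ccs_label
H660,10,92,Otitis media
H669,10,92,Otitis media
3820,9,92,Otitis media
3829,9,92,Otitis media
J010,10,121,Sinusitis
J019,10,121,Sinusitis
4610,9,121,Sinusitis
4619,9,121,Sinusitis
J159,10,122,Pneumonia
J189,10,122,Pneumonia
4829,9,122,Pneumonia
486,9,122,Pneumonia
J101,10,123,Influenza
J111,10,123,Influenza
4871,9,123,Influenza
48811,9,123,Influenza
J0300,10,124,Acute tonsillitis
J0390,10,124,Acute tonsillitis
4630,9,124,Acute tonsillitis
J205,10,125,Acute bronchitis
J209,10,125,Acute bronchitis
4660,9,125,Acute bronchitis
J00,10,126,Other upper respiratory infection
J069,10,126,Other upper respiratory infection
460,9,126,Other upper respiratory infection
4659,9,126,Other upper respiratory infection
N390,10,159,Urinary tract infection
5990,9,159,Urinary tract infection
B349,10,76,Viral infection unspecified
0799,9,76,Viral infection unspecified
L0390,10,197,Skin and subcutaneous infection
6829,9,197,Skin and subcutaneous infection
Z0000,10,10,Well-child examination
Z00129,10,10,Well-child examination
V202,9,10,Well-child examination
V700,9,10,Well-child examination
J4520,10,128,Asthma
J45909,10,128,Asthma
49300,9,128,Asthma
49390,9,128,Asthma
H903,10,94,Hearing loss
H9190,10,94,Hearing loss
3890,9,94,Hearing loss
38910,9,94,Hearing loss
D809,10,57,Immunity disorder
2790,9,57,Immunity disorder
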