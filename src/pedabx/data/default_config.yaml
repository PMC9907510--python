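abx_class_probs:
  cephalosporins: 0.25
  macrolides: 0.2
  penicillins: 0.55
age_band_rates:
- - 0
  - 180
  - 0.6
- - 180
  - 730
  - 1.9
- - 730
  - 1825
  - 1.2
birth_year_range:
- 2008
- 2013
census_counts:
  CA:
    F: 1300934
    M: 1230066
  FL:
    F: 551522
    M: 521478
  GA:
    F: 353118
    M: 333882
  IL:
    F: 426620
    M: 403380
  MI:
    F: 306344
    M: 289656
  NC:
    F: 324848
    M: 307152
  NY:
    F: 593670
    M: 561330
  OH:
    F: 370594
    M: 350406
  PA:
    F: 374706
    M: 354294
  TX:
    F: 990992
    M: 937008
condition_multipliers:
  cardiac: 1.0
  craniofacial: 1.0
  dermatological: 1.0
  endocrinological: 1.0
  gastrointestinal: 1.0
  genetic: 1.0
  genitourinary: 1.0
  hematological: 1.0
  immunological: 1.0
  malignancy: 1.0
  mental_health: 1.0
  metabolic: 1.0
  musculoskeletal: 1.0
  neurological: 1.0
  ophthalmological: 1.0
  otolaryngological: 1.0
  otologic: 1.0
  pulmonary_respiratory: 2.0480014319983897
  renal: 1.0
condition_prevalences:
  cardiac: 0.023
  craniofacial: 0.072
  dermatological: 0.068
  endocrinological: 0.009
  gastrointestinal: 0.021
  genetic: 0.003
  genitourinary: 0.089
  hematological: 0.01
  immunological: 0.012
  malignancy: 0.004
  mental_health: 0.003
  metabolic: 0.043
  musculoskeletal: 0.01
  neurological: 0.024
  ophthalmological: 0.091
  otolaryngological: 0.002
  otologic: 0.018
  pulmonary_respiratory: 0.183
  renal: 0.011
decoy_visit_rate: 2.0
fill_lag_probs:
- 0.5
- 0.2
- 0.1
- 0.07
- 0.05
- 0.04
- 0.02
- 0.02
frailty_shape: 1.4345402941372154
n_children: 20000
nonabx_fill_rate: 0.5
p_respiratory: 0.71
seed: 0
sex_probs:
  F: 0.514
  M: 0.486
state_probs:
  CA: 0.23258592170556883
  FL: 0.09860319794155487
  GA: 0.06313177724682963
  IL: 0.07627274398088586
  MI: 0.05476934387061202
  NC: 0.05807755927219261
  NY: 0.10613857746737732
  OH: 0.06625620290387796
  PA: 0.06699136188200698
  TX: 0.17717331372909392
unlinked_fill_prob: 0.0
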