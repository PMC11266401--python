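age_band_probs:
- 0.0295
- 0.045
- 0.124
- 0.2667
- 0.2744
- 0.1736
- 0.0868
age_bands:
- - 18
  - 30
- - 30
  - 40
- - 40
  - 50
- - 50
  - 60
- - 60
  - 70
- - 70
  - 80
- - 80
  - 91
case_targets:
  emergency:
    cost:
    - 4500.0
    - 6300.0
    - 4000.0
    - 5180.0
    cost_shape: 1.2
    count_dispersion: 1.2
    hospital_days: null
    los_dispersion: 1.2
    med_frac: 0.15
    p_use:
    - 0.45
    - 0.18
    - 0.26
    - 0.4
    visits:
    - 0.75
    - 0.97
    - 0.6
    - 0.68
  inpatient:
    cost:
    - 70000.0
    - 108450.0
    - 53400.0
    - 50000.0
    cost_shape: 1.0
    count_dispersion: 1.2
    hospital_days:
    - 8.0
    - 12.02
    - 7.45
    - 7.9
    los_dispersion: 1.2
    med_frac: 0.33
    p_use:
    - 0.5
    - 0.2
    - 0.22
    - 0.38
    visits:
    - 0.85
    - 1.15
    - 0.506
    - 0.56
  outpatient:
    cost:
    - 100000.0
    - 179740.0
    - 118000.0
    - 97000.0
    cost_shape: 1.5
    count_dispersion: 1.6
    hospital_days: null
    los_dispersion: 1.2
    med_frac: 0.4702
    p_use:
    - 0.999
    - 0.92
    - 0.99
    - 0.999
    visits:
    - 28.0
    - 37.88
    - 30.0
    - 26.5
comorbidity_prevalence:
  case:
    cardiac: 0.2729
    liver: 0.0233
    malignancy: 0.2341
    neuropathy: 0.0248
    pulmonary: 0.0651
    renal: 0.2171
  comparator:
    cardiac: 0.1211
    liver: 0.0009
    malignancy: 0.0443
    neuropathy: 0.0051
    pulmonary: 0.0026
    renal: 0.038
comparator_pool_size: null
comparator_targets:
  emergency:
    cost:
    - 1570.0
    cost_shape: 1.2
    count_dispersion: 1.2
    hospital_days: null
    los_dispersion: 1.2
    med_frac: 0.1
    p_use:
    - 0.07
    visits:
    - 0.35
  inpatient:
    cost:
    - 15510.0
    cost_shape: 1.0
    count_dispersion: 1.2
    hospital_days:
    - 2.185
    los_dispersion: 1.2
    med_frac: 0.18
    p_use:
    - 0.06
    visits:
    - 0.2875
  outpatient:
    cost:
    - 30490.0
    cost_shape: 1.5
    count_dispersion: 1.6
    hospital_days: null
    los_dispersion: 1.2
    med_frac: 0.3
    p_use:
    - 0.8
    visits:
    - 18.66
covariate_effects:
  cost_age10: 0.05
  cost_comorbidity:
    cardiac: 0.2
    liver: 0.1
    malignancy: 0.25
    neuropathy: 0.1
    pulmonary: 0.1
    renal: 0.2
  cost_male: 0.0
  use_age10: 0.12
  use_comorbidity:
    cardiac: 0.35
    liver: 0.2
    malignancy: 0.3
    neuropathy: 0.2
    pulmonary: 0.25
    renal: 0.3
  use_male: -0.08
data_end: '2019-12-31'
index_window:
- '2016-01-01'
- '2018-12-31'
mortality_breakpoints:
- 90.0
- 182.0
- 1095.0
mortality_targets:
  case:
    90.0: 0.084
    182.0: 0.121
    1095.0: 0.188
  comparator:
    182.0: 0.009
    1095.0: 0.037
n_cases: 645
p_male: 0.5907
plant_patterns: true
region_probs:
- 0.261973802619738
- 0.2666733326667333
- 0.21857814218578142
- 0.1131886811318868
- 0.017098290170982904
- 0.12248775122487751
regions:
- Taipei
- North
- Central
- South
- East
- Kaohsiung-PingTung
rng_seed: 20160101
trap_rate: 0.01
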