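cardiac:
  icd10:
  - I50
  - I42
  - I31
  icd9:
  - '428'
  - '425'
liver:
  icd10:
  - K72
  - K74
  - K76
  icd9:
  - '571'
  - '573'
malignancy:
  icd10:
  - C90
  - C34
  - C50
  - C18
  icd9:
  - '203'
  - '162'
neuropathy:
  icd10:
  - G62
  - G63
  - G90
  icd9:
  - '356'
  - '357'
pulmonary:
  icd10:
  - J44
  - J47
  - J84
  icd9:
  - '496'
  - '515'
renal:
  icd10:
  - N18
  - N04
  - N08
  icd9:
  - '585'
  - '581'
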