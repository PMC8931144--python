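# Default study-regime generator configuration: 24 interviews over a
# 22-value / 41-element vocabulary, heavy-tailed background co-occurrence,
# and a planted core of strong links spanning 13 values and 7 biophysical
# elements. Used for demos and end-to-end pipeline checks.
n_values: 22
n_biophysical: 41
n_interviews: 24
segments_per_interview:
  mean: 10.0
  dispersion: null
mentions_per_segment:
  mean: 12.0
  dispersion: null
background_concentration: 0.9
p_value_value: 0.35
seed: 1
planted_pairs:
  - [PETRELS, HAR, 150]
  - [SEA, PTL, 140]
  - [LAND_BIRDS, PTP, 110]
  - [SEA, PTP, 100]
  - [PETRELS, PTA, 90]
  - [LAND_BIRDS, STE, 90]
  - [GARDENS, CEC, 80]
  - [FISH, HAR, 80]
  - [SEA, STE, 75]
  - [LAND, PTA, 70]
  - [SHELLFISH, CEC, 65]
  - [GARDENS, HAR, 60]
  - [FISH, CEC, 60]
  - [SEA, GOV, 55]
  - [LAND_BIRDS, BIO, 55]
  - [PETRELS, TEA, 50]
  - [LAND, PTL, 50]
  - [SHELLFISH, HAR, 50]
  - [PTL, PTA, 120]
  - [PRE, STE, 110]
  - [GOV, STE, 100]
  - [PTP, PTL, 90]
  - [PRE, GOV, 80]
  - [BIO, STE, 70]
  - [OPE, GOV, 60]
  - [SPI, PTA, 60]
  - [CON, GOV, 55]
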