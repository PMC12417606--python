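{
  "registry_total": 3056306,
  "registry_boys": 1569082,
  "registry_girls": 1487224,
  "registry_asd": 14549,
  "registry_asd_boys": 12571,
  "registry_asd_girls": 1978,
  "pie_participants": 339968,
  "national_school_adjusted_prev_pct": [
    0.46,
    0.45,
    0.47
  ],
  "age_band_counts": {
    "6-8": 748406,
    "9-11": 767350,
    "12-14": 749693,
    "15-18": 790857
  },
  "rural_count": 238948,
  "ethnicity_counts": {
    "Mapuche": 176302,
    "Aymara": 20946,
    "Other": 21692,
    "None": 2837366
  },
  "fee_band_counts": {
    "Free": 2190359,
    "1.15-11.50": 1120,
    "11.51-28.75": 36477,
    "28.76-57.51": 206952,
    "57.52-115.01": 270875,
    ">115.02": 300521,
    "Missing": 50002
  },
  "ssas": {
    "population": 132242,
    "seed_accessors": 488,
    "blocked_pairs": 293,
    "matches": 233,
    "unmatched_patients": 1132,
    "unique_patients": 1365,
    "school_adjusted_prev_pct": [
      0.37,
      0.34,
      0.41
    ],
    "updated_adjusted_prev_pct": [
      1.22,
      1.16,
      1.28
    ],
    "updated_crude_prev_pct": [
      1.23,
      1.17,
      1.28
    ],
    "interrater_kappa": 0.97
  },
  "national_projection": {
    "updated_prev_pct": 1.31,
    "posited_cases": 40113,
    "unmet_cases": 25903
  }
}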