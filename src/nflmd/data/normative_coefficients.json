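{
  "schema": "nflmd-normative-coefficients",
  "version": 1,
  "units": {"intercept": "um", "age_slope": "um/year", "axlen_slope": "um/mm"},
  "reference_age_years": 50.0,
  "reference_axial_length_mm": 23.6,
  "floor_fraction": 0.45,
  "db_floor_clamp": -12.8,
  "coefficients": [
    {"sector_id": "overall",           "intercept": 188.0, "age_slope": -0.14, "axlen_slope": -3.38},
    {"sector_id": "inferior_quadrant", "intercept": 246.3, "age_slope": -0.10, "axlen_slope": -4.93},
    {"sector_id": "TU1", "intercept": 124.1, "age_slope": -0.14, "axlen_slope": -2.06},
    {"sector_id": "TU2", "intercept": 141.1, "age_slope": -0.13, "axlen_slope": -1.64},
    {"sector_id": "ST2", "intercept": 199.4, "age_slope": -0.26, "axlen_slope": -2.30},
    {"sector_id": "ST1", "intercept": 225.9, "age_slope": -0.12, "axlen_slope": -3.54},
    {"sector_id": "SN1", "intercept": 187.5, "age_slope": -0.08, "axlen_slope": -3.06},
    {"sector_id": "SN2", "intercept": 202.5, "age_slope": -0.29, "axlen_slope": -3.31},
    {"sector_id": "NU2", "intercept": 235.9, "age_slope": -0.32, "axlen_slope": -5.19},
    {"sector_id": "NU1", "intercept": 203.5, "age_slope": -0.17, "axlen_slope": -5.00},
    {"sector_id": "NL1", "intercept": 151.6, "age_slope": -0.07, "axlen_slope": -3.39},
    {"sector_id": "NL2", "intercept": 189.1, "age_slope": -0.13, "axlen_slope": -4.22},
    {"sector_id": "IN2", "intercept": 241.2, "age_slope": -0.19, "axlen_slope": -5.40},
    {"sector_id": "IN1", "intercept": 332.9, "age_slope": -0.07, "axlen_slope": -8.71},
    {"sector_id": "IT1", "intercept": 290.0, "age_slope": -0.05, "axlen_slope": -5.98},
    {"sector_id": "IT2", "intercept": 121.9, "age_slope": -0.10, "axlen_slope": 0.36},
    {"sector_id": "TL2", "intercept": 72.5,  "age_slope": -0.15, "axlen_slope": 0.51},
    {"sector_id": "TL1", "intercept": 89.0,  "age_slope": -0.03, "axlen_slope": -1.18}
  ]
}
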