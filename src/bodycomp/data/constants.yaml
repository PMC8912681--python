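# Child-specific conversion constants by sex and half-open age band [age_min, age_max).
#
# adp_density_constants: (c1, c2) of the two-compartment density equation
#   %FM = (c1 / Db - c2) * 100, Db in kg/L. Values follow the Lohman-style
#   age/sex tables commonly built into pediatric ADP software; they are
#   configuration defaults, not measured study values, and can be replaced
#   by any file with this schema.
# hydration_coefficients: assumed TBW/FFM ratio used to convert total body
#   water to fat-free mass, likewise Lohman-style pediatric defaults.
# adipose_density_kg_per_L: density used to turn MRI fat-voxel volume into mass.

adipose_density_kg_per_L: 0.92

adp_density_constants:
  male:
    - {age_min: 4,  age_max: 9,  c1: 5.38, c2: 4.97}
    - {age_min: 9,  age_max: 11, c1: 5.30, c2: 4.89}
    - {age_min: 11, age_max: 13, c1: 5.23, c2: 4.81}
    - {age_min: 13, age_max: 15, c1: 5.07, c2: 4.64}
    - {age_min: 15, age_max: 17, c1: 5.03, c2: 4.59}
    - {age_min: 17, age_max: 19, c1: 4.98, c2: 4.53}
  female:
    - {age_min: 4,  age_max: 9,  c1: 5.43, c2: 5.03}
    - {age_min: 9,  age_max: 11, c1: 5.35, c2: 4.95}
    - {age_min: 11, age_max: 13, c1: 5.25, c2: 4.84}
    - {age_min: 13, age_max: 15, c1: 5.12, c2: 4.69}
    - {age_min: 15, age_max: 17, c1: 5.07, c2: 4.64}
    - {age_min: 17, age_max: 19, c1: 5.05, c2: 4.62}

hydration_coefficients:
  male:
    - {age_min: 4,  age_max: 9,  coefficient: 0.768}
    - {age_min: 9,  age_max: 11, coefficient: 0.762}
    - {age_min: 11, age_max: 13, coefficient: 0.759}
    - {age_min: 13, age_max: 15, coefficient: 0.755}
    - {age_min: 15, age_max: 17, coefficient: 0.748}
    - {age_min: 17, age_max: 19, coefficient: 0.741}
  female:
    - {age_min: 4,  age_max: 9,  coefficient: 0.776}
    - {age_min: 9,  age_max: 11, coefficient: 0.770}
    - {age_min: 11, age_max: 13, coefficient: 0.770}
    - {age_min: 13, age_max: 15, coefficient: 0.768}
    - {age_min: 15, age_max: 17, coefficient: 0.760}
    - {age_min: 17, age_max: 19, coefficient: 0.755}
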