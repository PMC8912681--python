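# Default synthetic-cohort scenario: four age-sex strata (n summing to 288)
# with marginal means/SDs shaped like the emulated pediatric cohort, and a
# per-method error model (constant bias kg, proportional slope per kg of
# true fat mass, residual SD kg) shaped like the corresponding total-sample
# agreement results. fat_fraction is the 4-C fat mass divided by weight.

strata:
  - {sex: female, age_group: children,    n: 63, age_mean: 8.1,  age_sd: 1.8,
     weight_mean_kg: 26.1, weight_sd_kg: 8.1,  height_mean_cm: 123.5, height_sd_cm: 14.7,
     fat_fraction_mean: 0.194, fat_fraction_sd: 0.087}
  - {sex: male,   age_group: children,    n: 54, age_mean: 8.4,  age_sd: 1.7,
     weight_mean_kg: 28.6, weight_sd_kg: 8.1,  height_mean_cm: 127.9, height_sd_cm: 11.1,
     fat_fraction_mean: 0.191, fat_fraction_sd: 0.090}
  - {sex: female, age_group: adolescents, n: 92, age_mean: 14.5, age_sd: 2.1,
     weight_mean_kg: 51.2, weight_sd_kg: 12.0, height_mean_cm: 155.1, height_sd_cm: 7.3,
     fat_fraction_mean: 0.268, fat_fraction_sd: 0.084}
  - {sex: male,   age_group: adolescents, n: 79, age_mean: 14.8, age_sd: 2.0,
     weight_mean_kg: 53.9, weight_sd_kg: 11.6, height_mean_cm: 163.4, height_sd_cm: 10.3,
     fat_fraction_mean: 0.174, fat_fraction_sd: 0.089}

errors:
  SF:  {constant_bias_kg: 0.7,  proportional_slope: -0.10,  residual_sd_kg: 2.5}
  DXA: {constant_bias_kg: 3.0,  proportional_slope: -0.006, residual_sd_kg: 2.1}
  ADP: {constant_bias_kg: -0.9, proportional_slope: -0.05,  residual_sd_kg: 2.0}
  D2O: {constant_bias_kg: -0.4, proportional_slope: 0.09,   residual_sd_kg: 2.5}
  MRI: {constant_bias_kg: 4.0,  proportional_slope: -0.10,  residual_sd_kg: 2.8}

options:
  size_fatness_corr: 0.5     # within-stratum correlation of weight and fat fraction
  bmc_ffm_fraction: 0.048    # BMC generated as this fraction of FFM (simulation convenience)
  tgv_weight_fraction: 0.05  # thoracic gas volume as a fraction of body weight
  mri_voxel_volume_L: 1.35e-05
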