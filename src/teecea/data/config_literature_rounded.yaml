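# Alternate preset: identical to default_config.yaml except that the
# fatal-stroke share of early mortality and the non-fatal stroke fraction use
# the rounded literature figures (15% of cardiac mortality attributed to fatal
# stroke; 38% of strokes fatal, hence 62% non-fatal) instead of the tabulated
# 13.2% / 80.8%. Treated as fixed here because no distribution accompanies the
# rounded figures.
parameters:
  p_death_is_stroke: {value: 0.15}
  p_stroke_nonfatal: {value: 0.62}
  p_stroke_embolic: {value: 0.710, dist: {family: beta, params: [107, 44]}}
  sens_mp: {value: 0.31, dist: {family: beta, params: [33, 73]}}
  spec_mp: {value: 0.98, dist: {family: beta, params: [179, 4]}}
  sens_tee: {value: 0.97, dist: {family: beta, params: [124, 4]}}
  spec_tee: {value: 0.80, dist: {family: beta, params: [173, 44]}}
  rr_adaptation: {value: 0.46, dist: {family: lognormal, params: [-0.864, 0.392]}}
  p_major_adaptation: {value: 0.027, dist: {family: beta, params: [163, 5888]}}
  excess_mortality_under61: {value: 0.0118, dist: {family: uniform, params: [0.0082, 0.0142]}}
  excess_mortality_61to70: {value: 0.0233, dist: {family: uniform, params: [0.0195, 0.0271]}}
  excess_mortality_over70: {value: 0.0435, dist: {family: uniform, params: [0.0349, 0.0524]}}
  utility_post_stroke: {value: 0.439, dist: {family: triangular, params: [0.186, 0.439, 0.653]}}
  utility_no_complication: {value: 1.0}
  cost_death: {value: 2736, dist: {family: uniform, params: [1368, 5471]}}
  cost_fatal_stroke: {value: 2736, dist: {family: uniform, params: [1368, 5471]}}
  cost_tee_device: {value: 212, dist: {family: gamma, params: [198.40, 1.06855]}}
  cost_surgery_base: {value: 15628}
  cost_surgery_major_adaptation: {value: 23886}
  cost_nonfatal_stroke_acute: {value: 9000}
  cost_post_stroke_annual: {value: 7500}
  discount_costs: {value: 0.040}
  discount_effects: {value: 0.015}
  mortality_calibration_reduction: {value: 0.71}

euroscore:
  intercept: -4.789594
  coefficients:
    age_per_5yr_over_60: 0.0666354
    female: 0.3304052
    extracardiac_arteriopathy: 0.6558917
    unstable_angina: 0.5677075
    recent_mi: 0.5460218
    emergency: 0.7127953
  arteriopathy_or: 1.926878

subgroups:
  - {sex: male,   age: 55, prevalence: 0.10, early_mortality: 0.0104}
  - {sex: male,   age: 55, prevalence: 0.15, early_mortality: 0.0108}
  - {sex: female, age: 55, prevalence: 0.10, early_mortality: 0.0141}
  - {sex: female, age: 55, prevalence: 0.15, early_mortality: 0.0146}
  - {sex: male,   age: 65, prevalence: 0.20, early_mortality: 0.0161}
  - {sex: male,   age: 65, prevalence: 0.30, early_mortality: 0.0171}
  - {sex: female, age: 65, prevalence: 0.20, early_mortality: 0.0214}
  - {sex: female, age: 65, prevalence: 0.30, early_mortality: 0.0228}
  - {sex: male,   age: 75, prevalence: 0.40, early_mortality: 0.0318}
  - {sex: male,   age: 75, prevalence: 0.50, early_mortality: 0.0336}
  - {sex: female, age: 75, prevalence: 0.40, early_mortality: 0.0413}
  - {sex: female, age: 75, prevalence: 0.50, early_mortality: 0.0434}
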