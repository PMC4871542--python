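# Base-case model inputs (Int$, PPP 2013). Life table, prevalence tables and
# the PSA block are omitted here and filled with the documented defaults:
# synthetic tables, and all-fixed sampling specs.
risk:
  intercept_nonfatal: -9.54
  intercept_fatal: -10.67
  beta_age: 0.07
  beta_sex: 0.55
  functional_form: log_rate
epi:
  uptake: {female: 0.62, male: 0.48}
  incidence_prob: {female: 0.0065, male: 0.0164}
  p_acute_to_fatal: 0.008
  cvd_death_fraction: 0.25
  rr_acute: 0.72
  rr_death: 0.82
  composite_stroke_weight: 0.78
  symptomatic_diagnosis_prob: 0.0
econ:
  cost_screen_round: 6.05
  cost_htn_treat_year: 70.82
  cost_cvd_acute_year: 3723.24
  cost_cvd_stable_year: 79.39
  utility_healthy: 0.93
  utility_htn: {male: 0.74, female: 0.71}
  utility_acute: 0.67
  utility_stable: {male: 0.72, female: 0.71}
  discount_cost: 0.03
  discount_qaly: 0.0
  ppp_rate: 7546.6
  gdp_per_capita: 5294.0
  wtp_multiplier: 3.0
alt_utilities_gbd: {healthy: 0.957, htn: 0.835, acute: 0.685, stable: 0.717}
provenance:
  risk: published age/sex risk-equation coefficients
  epi: published point estimates; cvd_death_fraction synthetic default
  econ: published unit costs and utilities
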