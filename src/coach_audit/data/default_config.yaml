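# Default synthetic-cohort configuration, calibrated to the audited cohort's
# published marginals (printed count / 4307 for each item).  Hierarchy defaults
# to 6 regions x 10 centers x 80 cases per center.  Probabilities suffixed
# "_given_*" are conditionals; the generator derives the remaining conditionals
# from the marginals so pooled rates reproduce the configured values.
schema: coach-audit-generator/1
n_regions: 6
centers_per_region: 10
cases_per_center: 80
center_effect_sd: 0.4
region_effect_sd: 0.2
gold_classifiable_fraction: 0.101
rural_population_range: [2000, 600000]
seed: 0
item_prevalences:
  correct_diagnosis_components: 0.176
  spiro_audited_post_bd: 0.09          # P(post-BD | audited-visit spirometry present)
  spiro_diagnostic_present: 0.40
  spiro_diagnostic_post_bd: 0.30       # P(post-BD | diagnostic-visit spirometry present)
  dyspnea_registered: 0.190
  dyspnea_mmrc_registered: 0.111
  cat_registered: 0.011
  cough_sputum_registered: 0.255
  chronic_bronchitis: 0.183
  sputum_color_given_cb: 0.454
  asthma_symptoms_registered: 0.199
  exacerbations_registered: 0.814
  smoking_status_registered: 0.435
  exercise_registered: 0.453
  influenza_vacc_registered: 0.877
  pneumococcal_vacc_registered: 0.694
  adverse_effects_registered: 0.040
  adherence_registered: 0.142
  inhaler_satisfaction_registered: 0.045
  quit_advice: 0.244
  exercise_advice: 0.222
  influenza_vaccinated: 0.666
  pneumococcal_vaccinated: 0.376
  duplicate_prescription: 0.020
  exposure_passive: 0.02
  exposure_occupational: 0.05
  exposure_biomass: 0.03
  pack_years_registered: 0.70
  psychiatric_drugs: 0.116
  eyedrops: 0.013
  roflumilast: 0.013
  mucolytic: 0.022
  antibiotic: 0.007
  methylxanthine: 0.023
  ltot: 0.041
  hmv: 0.008
  nebulized: 0.028
categorical_prevalences:
  sex: {male: 0.733, female: 0.267}
  smoking_status: {active: 0.267, ex: 0.262, never: 0.134, unknown: 0.337}
  regimen:
    none: 0.336
    one_LABD: 0.152
    LABA_LAMA: 0.091
    ICS_alone: 0.015
    ICS_plus_one_LABD: 0.178
    LAMA_ICS_other: 0.009
    triple: 0.219
  gold_group: {A: 0.454, B: 0.197, C: 0.151, D: 0.198}
condition_prevalences:
  chronic_pulmonary_disease: 1.0
  coronary_artery_disease: 0.13
  congestive_heart_failure: 0.10
  atrial_fibrillation: 0.09
  peripheral_vascular_disease: 0.05
  cerebrovascular_disease: 0.05
  diabetes: 0.18
  dementia: 0.03
  renal_disease: 0.06
  peptic_ulcer_disease: 0.04
  lung_cancer: 0.02
  other_cancer: 0.08
  anxiety: 0.10
  sleep_apnea: 0.047
  prostatic_hyperplasia: 0.168         # realized in men only
continuous_params:
  age_years: {mean: 71.1, sd: 12.7}
  fev1_ml: {mean: 1690, sd: 694}
  fev1_pct: {mean: 64.3, sd: 22.8}
  fev1_fvc_pct: {mean: 62.3, sd: 13.2}
  bmi: {mean: 29.2, sd: 5.5}
  pack_years: {mean: 44.2, sd: 48.6}
continuous_kappa:
  default: 0.25
  fev1_ml: 0.0
  fev1_pct: 0.0
  fev1_fvc_pct: 0.0
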