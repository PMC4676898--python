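# Coefficient-file template for the linked-equation COPD progression model.
#
# Fill each block from your estimated risk equations (e.g. the ECLIPSE
# clinical-endpoint and TORCH resource-use equations).  One block per
# outcome; delete a block to carry that outcome forward unchanged.
#
# link: identity | log | logit
#   - exacerbation rates and resource counts conventionally use log
#   - symptom proportions use logit
#   - FEV1 / SGRQ / 6MWT use identity
#   - survival: log = log annual hazard (exponential within-cycle survival),
#     identity = annual hazard, logit = annual death probability
# mode: direct (predicts the annual-unit value) | change (predicts an annual
#   increment added to the previous level, scaled by cycle length)
# coefficients: covariate name -> value.  Valid covariate names are the
#   baseline fields (female, age, bmi_low, bmi_medium, bmi_high,
#   cvd_comorbidity, other_comorbidity, prior_exacerbations,
#   prior_severe_fraction, history_any_exacerbation, mmrc_ge2,
#   current_smoker, height, fibrinogen, sgrq0, fev1pp0, walk0, male) and the
#   time-updated state fields (fev1_ml, fev1pp, sgrq, p_dyspnoea,
#   p_cough_sputum, walk_m, annual_moderate_rate, annual_severe_rate, age).
# se: standard errors for second-order PSA sampling ("intercept" for the
#   intercept's own SE); omit or leave empty to hold a parameter fixed.

equations:
  - outcome: fev1
    link: identity
    mode: change
    intercept: 0.0
    coefficients: {}
    se: {}
  - outcome: moderate_exac_rate
    link: log
    mode: direct
    intercept: 0.0
    coefficients: {}
    se: {}
  - outcome: severe_exac_rate
    link: log
    mode: direct
    intercept: 0.0
    coefficients: {}
    se: {}
  - outcome: dyspnoea
    link: logit
    mode: direct
    intercept: 0.0
    coefficients: {}
    se: {}
  - outcome: cough_sputum
    link: logit
    mode: direct
    intercept: 0.0
    coefficients: {}
    se: {}
  - outcome: walk
    link: identity
    mode: change
    intercept: 0.0
    coefficients: {}
    se: {}
  - outcome: sgrq
    link: identity
    mode: change
    intercept: 0.0
    coefficients: {}
    se: {}
  - outcome: survival
    link: log
    mode: direct
    intercept: -20.0   # ~zero hazard until filled in
    coefficients: {}
    se: {}
  - outcome: resource_use.hospitalisations
    link: identity
    mode: direct
    intercept: 0.0
    coefficients: {}
    se: {}
  - outcome: resource_use.ward_days
    link: identity
    mode: direct
    intercept: 0.0
    coefficients: {}
    se: {}
  - outcome: resource_use.icu_days
    link: identity
    mode: direct
    intercept: 0.0
    coefficients: {}
    se: {}
  - outcome: resource_use.er_visits
    link: identity
    mode: direct
    intercept: 0.0
    coefficients: {}
    se: {}
  - outcome: resource_use.outpatient_visits
    link: identity
    mode: direct
    intercept: 0.0
    coefficients: {}
    se: {}
  - outcome: resource_use.home_visits_day
    link: identity
    mode: direct
    intercept: 0.0
    coefficients: {}
    se: {}
  - outcome: resource_use.home_visits_night
    link: identity
    mode: direct
    intercept: 0.0
    coefficients: {}
    se: {}
  - outcome: resource_use.office_visits
    link: identity
    mode: direct
    intercept: 0.0
    coefficients: {}
    se: {}
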