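# Demonstration run: an Empareg-like placebo-proxy emulation on a synthetic
# biobank cohort with confounding by indication.
seed: 1
cohort:
  n_individuals: 20000
  pgs_confounder_r2:
    t2d: 0.4
    bmi: 0.4
    hba1c: 0.3
    chd: 0.3
  initiation_log_odds: {t2d: 1.0, bmi: 0.7, hba1c: 0.5}
  prescription_log_odds: {bmi: 0.5, chd: 0.4}
  true_treatment_log_hr: -0.357   # HR 0.70
  baseline_hazard: 0.08           # events per person-year
  confounder_log_hr: {t2d: 0.3, bmi: 0.3, chd: 0.4}
protocol:
  name: demo-cardio
  comparator_type: noninitiator
  eligibility_rules:
    - {covariate: t2d, require: true}
  covariates_for_ps: [bmi, hba1c, chd, ldl, sbp, crp]
  caliper: 0.1
  rct_reference: [0.86, 0.74, 0.99]
balance:
  alpha: 0.05
proxy_sim:
  r2_values: [0.01, 0.05, 0.1, 0.2, 0.3, 0.5]
  conf_fracs: [0.1, 0.2, 0.3, 0.5]
  n: 20000
  iterations: 20
mr:
  n_variants_per_trait: 50
  n_gwas: 200000
  effect_sd: 0.03
enrichment:
  outcome_trait: chd
  q: 0.25
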