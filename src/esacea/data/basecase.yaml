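# Base-case model configuration: epoetin-beta vs darbepoetin-alfa for anemia
# in chronic hemodialysis patients.  Clinical inputs are the observed arm
# summaries (success counts, event counts, Hb distributions); cost inputs are
# the direct-medical-cost items in USD per patient per year; utilities and
# transition dynamics are model inputs documented in docs/methods.md.

currency:
  sar_per_usd: 3.77

arms:
  darbepoetin-alfa:
    csr: {n_success: 124, n: 194}
    cv_event: {n_events: 19, n: 194}
    annual_cost_usd: 12319.41
    utilities: {success: 0.70, failure: 0.55}
    hb: {mean: 10.68, sd: 0.98}
    cost_profile:
      staffing:
        medical_consultant: 3405.6
        medical_specialist: 2311.2
        nutritional_specialist: 1542.0
        pharmacist: 1455.6
        social_specialist: 1180.8
      drug_cost: 6638.1
      hospitalization: 19050.759
    markov:
      p_death_dying: 1.0
      state_utility: [0.55, 0.70, 0.50, 0.45, 0.0]

  epoetin-beta:
    csr: {n_success: 78, n: 97}
    cv_event: {n_events: 3, n: 97}
    annual_cost_usd: 919.47
    utilities: {success: 0.70, failure: 0.55}
    hb: {mean: 11.63, sd: 0.32}
    cost_profile:
      staffing:
        medical_consultant: 3405.6
        medical_specialist: 2311.2
        nutritional_specialist: 1542.0
        pharmacist: 1455.6
        social_specialist: 1180.8
      drug_cost: 915.2
      hospitalization: 19155.7984
    markov:
      p_death_dying: 1.0
      state_utility: [0.55, 0.70, 0.50, 0.45, 0.0]

markov:
  cycle_length_days: 28
  discount_rate_annual: 0.0
  start_age_years: 55
  max_age_years: 100

tree:
  reference: darbepoetin-alfa
  intervention: epoetin-beta
  horizon_years: 1.0
  use_markov_payoffs: false

# Input-uncertainty distributions for the PSA: log-normal for costs
# (CV 0.10), truncated normal for success probabilities with sd set to the
# binomial standard error of the observed counts.
distributions:
  - path: arms.darbepoetin-alfa.annual_cost_usd
    family: lognormal
    cv: 0.10
  - path: arms.epoetin-beta.annual_cost_usd
    family: lognormal
    cv: 0.10
  - path: arms.darbepoetin-alfa.csr
    family: normal
    sd: 0.0345
    bounds: [0.0, 1.0]
  - path: arms.epoetin-beta.csr
    family: normal
    sd: 0.0403
    bounds: [0.0, 1.0]

sensitivity:
  one_way:
    - {path: arms.epoetin-beta.annual_cost_usd, low: 689.60, high: 1149.34, outcome: delta_cost}
    - {path: arms.darbepoetin-alfa.annual_cost_usd, low: 9239.56, high: 15399.26, outcome: delta_cost}
    - {path: arms.epoetin-beta.csr, low: 0.72, high: 0.88, outcome: delta_effect}
    - {path: arms.darbepoetin-alfa.csr, low: 0.57, high: 0.71, outcome: delta_effect}

run:
  seed: 20201204
  n_samples: 50000
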