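# US base case, 2020 USD. Probabilities are per 3-month cycle.
# Per-band decline probabilities interpolate the published 3.2-8.9%/cycle
# range linearly, worsening with lower FVC; override per band as needed.
# baseline_hazard is the synthetic exponential stand-in for untreated
# all-cause mortality, calibrated so the symptom-management arm yields
# 3.78 discounted lifetime QALYs.
global:
  cycle_years: 0.25
  discount_rate: 0.03
  wtp: 100000.0
  exacerbation_prob: 0.0197
  post_ae_mortality_multiplier: {mean: 1.40, sd: 0.20}
  ae_episode_cost: {mean: 14731.0, sd: 4026.0}
  annual_followup_cost: {mean: 12291.0, sd: 710.0}
  disutility_first_cycle: {mean: 0.140, sd: 0.047}
  disutility_subsequent: {mean: 0.078, sd: 0.032}
  horizon_years: null
  psa_n: 10000
  seed: 12345
  start_band: "80-89.9"
states:
  - {label: "90-110", fvc_low: 90.0, fvc_high: 110.0, utility_mean: 0.8380, utility_sd: 0.1782, decline_prob: 0.0320}
  - {label: "80-89.9", fvc_low: 80.0, fvc_high: 89.9, utility_mean: 0.8105, utility_sd: 0.2051, decline_prob: 0.0434}
  - {label: "70-79.9", fvc_low: 70.0, fvc_high: 79.9, utility_mean: 0.7800, utility_sd: 0.2244, decline_prob: 0.0548}
  - {label: "60-69.9", fvc_low: 60.0, fvc_high: 69.9, utility_mean: 0.7657, utility_sd: 0.2380, decline_prob: 0.0662}
  - {label: "50-59.9", fvc_low: 50.0, fvc_high: 59.9, utility_mean: 0.7387, utility_sd: 0.2317, decline_prob: 0.0776}
  - {label: "40-49.9", fvc_low: 40.0, fvc_high: 49.9, utility_mean: 0.6634, utility_sd: 0.2552, decline_prob: 0.0890}
  - {label: "death", fvc_low: 0.0, fvc_high: 40.0, utility_mean: 0.0, utility_sd: 0.0, decline_prob: 0.0}
strategies:
  - name: symptom_management
    annual_drug_cost: 0.0
    or_decline: {mean: 1.0, sd: 0.0}
    or_mortality: {mean: 1.0, sd: 0.0}
    or_exacerbation: {mean: 1.0, sd: 0.0}
  - name: pirfenidone
    annual_drug_cost: 113193.0
    or_decline: {mean: 0.55, sd: 0.09}
    or_mortality: {mean: 0.69, sd: 0.19}
    or_exacerbation: {mean: 1.10, sd: 0.58}
  - name: nintedanib
    annual_drug_cost: 112357.0
    or_decline: {mean: 0.54, sd: 0.08}
    or_mortality: {mean: 0.70, sd: 0.19}
    or_exacerbation: {mean: 0.56, sd: 0.18}
baseline_hazard:
  family: exponential
  rate_per_year: 0.155672378577292  # calibrated: SM arm -> 3.78 discounted QALYs
followup_components:
  oxygen_therapy: 8916.0
  pulmonary_office_visit: 890.0
  primary_care: 890.0
  pulmonary_function_test: 680.0
  echocardiogram: 401.0
  ct_chest: 241.0
  palliative_care: 160.0
  pulmonary_rehabilitation: 62.0
  six_minute_walk_test: 51.0
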