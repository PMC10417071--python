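# Default study configuration: three enteral nutrition support strategies
# (PEG gastrostomy, nasogastric tube feeding NTF, oral supplements ONS)
# in definitive chemoradiotherapy for esophageal squamous cell carcinoma.
# Group-level values are the published per-arm summaries (n = 63 per arm);
# categorical entries are stored as counts out of n so that generated
# proportions are exact fractions.  Costs in USD (1 USD = 6.37 CNY).

arms:
  - arm_label: PEG
    n: 63
    weight_change_mean: -1.4
    weight_change_sd: 4.4
    weight_category_counts: [18, 7, 38]    # gain / unchanged / loss
    albumin_ge35_count: 62
    crp_lt15_count: 38
    lymph_ge1_count: 11
    response_counts: [50, 12, 1, 0]        # CR / PR / SD / PD
    lrfs_1yr: 0.883
    os_1yr: 0.886
    cost_means:
      radiotherapy: 10086.04
      chemotherapy: 695.95
      nutrition_support: 1120.28
      antibiotics_emergencies: 332.98
      hospitalization_other: 4683.30       # balance to the 6-month total
    total_6mo_cost: 16918.55
    hospital_days_mean: 11.3
    age_range: [44, 87]
    sex_male_count: 47
    stage_counts: {IIA: 2, IIB: 5, III: 38, IVA: 18, IVB: 0}
    ecog_counts: {"0-1": 63, "2": 0}

  - arm_label: NTF
    n: 63
    weight_change_mean: -2.1
    weight_change_sd: 3.3
    weight_category_counts: [8, 26, 29]
    albumin_ge35_count: 56
    crp_lt15_count: 27
    lymph_ge1_count: 7
    response_counts: [36, 21, 2, 4]
    lrfs_1yr: 0.786
    os_1yr: 0.831
    cost_means:
      radiotherapy: 8519.56
      chemotherapy: 1362.66
      nutrition_support: 732.56
      antibiotics_emergencies: 1267.82
      hospitalization_other: 7241.32
    total_6mo_cost: 19123.92
    hospital_days_mean: 28.7
    age_range: [40, 75]
    sex_male_count: 54
    stage_counts: {IIA: 2, IIB: 0, III: 42, IVA: 17, IVB: 2}
    ecog_counts: {"0-1": 62, "2": 1}

  - arm_label: ONS
    n: 63
    weight_change_mean: -3.0
    weight_change_sd: 5.4
    weight_category_counts: [7, 21, 35]
    albumin_ge35_count: 51
    crp_lt15_count: 25
    lymph_ge1_count: 3
    response_counts: [34, 23, 4, 2]
    lrfs_1yr: 0.768
    os_1yr: 0.812
    cost_means:
      radiotherapy: 8377.22
      chemotherapy: 2248.82
      nutrition_support: 757.65
      antibiotics_emergencies: 1073.23
      hospitalization_other: 5942.09
    total_6mo_cost: 18399.01
    hospital_days_mean: 28.3
    age_range: [44, 80]
    sex_male_count: 50
    stage_counts: {IIA: 4, IIB: 3, III: 28, IVA: 25, IVB: 3}
    ecog_counts: {"0-1": 62, "2": 1}

# Trial design: one-sample t-test on mean percent weight change.
power:
  null_mean: -5.0
  alt_mean: -3.0
  sd: 5.0
  alpha_one_sided: 0.025
  power: 0.80
  dropout_rate: 0.15

# Three-group propensity-score matching on the logit scale.
match:
  covariates: [age, sex, stage, ecog]
  caliper_multiplier: 0.6
  replacement: false
  reference_arm: PEG

# 3-state Markov cohort model: disease-free / relapse / death,
# annual cycles over a lifetime horizon (median age 62 -> age 100).
markov:
  cycle_length: 1.0
  horizon_cycles: 38
  discount_rate: 0.03
  utilities: {disease_free: 0.80, relapse: 0.53, death: 0.0}
  state_costs: {disease_free: 500.0, relapse: 8000.0, death: 0.0}
  background_mortality: 0.01
  relapse_mortality: 0.5

# Cost-effectiveness comparison settings.
cea:
  wtp_grid: [0, 5000, 10000, 15000, 20000, 25000, 30000, 35000, 40000, 45000, 50000]
  headline_thresholds: [10000, 50000]
  cost_effective_threshold: 33962
  psa_draws: 10000
  seed: 20180515
  cny_per_usd: 6.37
  rel_sd_probability: 0.10
  rel_sd_utility: 0.10
  rel_sd_cost: 0.30
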