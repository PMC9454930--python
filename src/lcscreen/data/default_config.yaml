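# Default configuration: base-case model inputs for the asbestos-exposed
# cohort analysis.  Low/high bounds are read as 95% parametric intervals.
# Costs in euros (2020-era French health-insurance perspective).

parameters:
  # stage-at-diagnosis fractions (multiplied by the stratum incidence)
  stage_frac_localized_usual:      {family: normal, deterministic: 0.181, low: 0.171, high: 0.191}
  stage_frac_disseminated_usual:   {family: normal, deterministic: 0.819, low: 0.809, high: 0.829}
  stage_frac_localized_screen:     {family: normal, deterministic: 0.702, low: 0.694, high: 0.710}
  stage_frac_disseminated_screen:  {family: normal, deterministic: 0.298, low: 0.290, high: 0.306}

  # costs (euros)
  cost_usual_annual:               {family: gamma, deterministic: 26.0,    low: 26.0,    high: 73.0}
  cost_screen_round:               {family: gamma, deterministic: 189.0,   low: 147.0,   high: 232.0}
  cost_localized_surgical_oneoff:  {family: gamma, deterministic: 13390.0, low: 6337.0,  high: 20443.0}
  cost_localized_postsurgical_per2y: {family: gamma, deterministic: 19057.0, low: 16770.0, high: 21429.0}
  cost_disseminated_per2y:         {family: gamma, deterministic: 33132.0, low: 29357.0, high: 34305.0}
  cost_false_positive:             {family: gamma, deterministic: 2110.0,  low: 1716.0,  high: 2271.0}

  # health-state utilities
  utility_localized:               {family: beta, deterministic: 0.825, low: 0.793, high: 0.857}
  utility_disseminated:            {family: beta, deterministic: 0.573, low: 0.506, high: 0.640}
  utility_false_positive:          {family: beta, deterministic: 1.000, low: 0.970, high: 1.000}

  # structural scalars (fixed in the base probabilistic analysis)
  hr_overdiagnosis: 1.13
  fp_rate_per_screen: 0.012
  detected_to_interval_ratio: 2.8
  biennial_detection_factor: 1.5
  biennial_overdiagnosis: 1.0
  hr_death_localized: 2.68
  hr_death_disseminated: 8.38
  utility_healthy: 1.0
  discount_rate_annual: 0.03
  postsurgical_cycle_fraction: 1.0
  disseminated_cycle_fraction: 0.5

# Lung-cancer incidence per 1000 person-years by eligibility stratum and
# age band.  'null' marks bands with too few events to estimate a rate;
# the model falls back to the 60-75 band (flagged at lookup time).
incidence:
  total_population:      {all: 2.30, lt60: 2.61, b60_75: 2.21, gt75: 2.12,
                          smoking: any, exposure: any, plaques: false, asbestosis: false}
  smokers:               {all: 6.04, lt60: 6.41, b60_75: 5.57, gt75: null,
                          smoking: current, exposure: any, plaques: false, asbestosis: false}
  ever_smokers:          {all: 2.78, lt60: 3.22, b60_75: 2.30, gt75: 1.85,
                          smoking: ever, exposure: any, plaques: false, asbestosis: false}
  high_exposure:         {all: 2.90, lt60: 3.03, b60_75: 2.83, gt75: 2.64,
                          smoking: any, exposure: high, plaques: false, asbestosis: false}
  intermediate_exposure: {all: 2.20, lt60: 2.49, b60_75: 2.15, gt75: 1.91,
                          smoking: any, exposure: intermediate, plaques: false, asbestosis: false}
  high_exposure_smokers: {all: 7.07, lt60: 6.36, b60_75: 7.82, gt75: null,
                          smoking: current, exposure: high, plaques: false, asbestosis: false}
  pleural_plaques:       {all: 2.31, lt60: 2.42, b60_75: 2.25, gt75: 2.80,
                          smoking: any, exposure: any, plaques: true, asbestosis: false}
  asbestosis:            {all: 5.00, lt60: null, b60_75: 6.06, gt75: null,
                          smoking: any, exposure: any, plaques: false, asbestosis: true}

# Cohort composition targets (fractions) for the synthetic cohort generator.
cohort:
  n_subjects: 14218
  male_fraction: 0.948
  age_bands:            # entry-age mix
    lt60: 0.234
    b60_75: 0.738
    gt75: 0.028
  smoking:              # renormalized over subjects with known status
    never: 0.300
    former: 0.615
    current: 0.085
  exposure:
    low: 0.075
    intermediate: 0.680
    high: 0.245
  pleural_plaques_fraction: 0.18
  asbestosis_fraction: 0.03
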