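simulate:
  sites:
  - name: Cyprus
    country: Cyprus
    home_lat: 35.17
    home_lon: 33.36
    n_participants: 10
    n_participants_prior_year: 0
    baseline_home_fraction: 0.44
    level_home_fraction_shift:
    - 0.414
    - 0.487
    - 0.452
    baseline_steps_mean: 8996.0
    level_steps_shift:
    - -2531.0
    - -3638.0
    - -3644.0
    weekend_home_delta_baseline: 0.109
    weekend_home_delta_lockdown: -0.08
    weekend_steps_delta_baseline: -1002.0
    weekend_steps_delta_lockdown: 400.0
    age_effect_home: 0.014
    age_effect_steps: -378.0
    gender_effect_steps: 1024.0
    humidity_effect_steps: -29.0
    year_effect_home: -0.006
    year_effect_steps: -1560.0
    temp_mean_c: 16.0
    temp_sd_c: 3.5
    rh_mean_pct: 65.0
    rh_sd_pct: 10.0
    weather_ar1: 0.6
    n_dds_days:
      '2020': 5
      '2019': 4
    p_wheezing: 0.66
    p_preventive_medication: 0.19
    p_unscheduled_visits: 0.64
    p_er_visits: 0.19
  - name: Greece
    country: Greece
    home_lat: 35.34
    home_lon: 25.13
    n_participants: 10
    n_participants_prior_year: 0
    baseline_home_fraction: 0.524
    level_home_fraction_shift:
    - 0.143
    - 0.231
    - 0.32
    baseline_steps_mean: 8527.0
    level_steps_shift:
    - -1191.0
    - -2337.0
    - -1961.0
    weekend_home_delta_baseline: 0.083
    weekend_home_delta_lockdown: -0.013
    weekend_steps_delta_baseline: -1212.0
    weekend_steps_delta_lockdown: 500.0
    age_effect_home: -0.01
    age_effect_steps: 0.0
    gender_effect_steps: 1064.0
    humidity_effect_steps: -2.0
    year_effect_home: -0.007
    year_effect_steps: -2791.0
    temp_mean_c: 15.0
    temp_sd_c: 3.5
    rh_mean_pct: 68.0
    rh_sd_pct: 10.0
    weather_ar1: 0.6
    n_dds_days:
      '2020': 1
      '2019': 2
    p_wheezing: 0.4
    p_preventive_medication: 0.22
    p_unscheduled_visits: 0.27
    p_er_visits: 0.33
  study_windows:
  - year: 2020
    start: '2020-03-01'
    end: '2020-03-28'
  age_min: 6.0
  age_max: 11.0
  age_center: 9.0
  male_fraction: 0.57
  gps_dropout_prob_indoor: 0.55
  gps_dropout_prob_outdoor: 0.15
  nonwear_day_prob: 0.1
  hr_present_prob: 0.92
  noise_sd_home: 0.08
  participant_sd_home: 0.05
  noise_sd_steps: 2200.0
  participant_sd_steps: 1000.0
  geofence_radius_m: 100.0
  home_fix_max_m: 80.0
  away_fix_min_m: 150.0
  away_fix_max_m: 2000.0
  seed: 0
intervals_csv: null
participants_csv: null
weather_csv: null
dds_csv: null
calendar_yaml: null
radius_m: 100.0
harmonic_period_days: 30.44
weather_interp_limit_days: 2
contrast_adjustment: bonferroni
out_dir: demo_out
seed: 0
log_level: INFO
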