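# Point tables and thresholds for the four dementia risk models.
#
# Everything here can be overridden at run time; in particular the ANU-ADRI
# age-by-sex grid ships only its published endpoints (0 points for men under
# 65, 41 for women 90 and over) -- the interior values are a monotone
# synthetic interpolation, clearly marked, to be replaced with the original
# instrument's values where available.

caide:
  age: {mid_min: 47, mid_max: 53, mid: 3, old: 4}   # <47: 0, 47-53: 3, >53: 4
  sex_male: 1
  education_bands: {low_max: 6, mid_max: 9, low: 3, mid: 2, high: 0}
  sbp_over_140: 2
  bmi_over_30: 2
  cholesterol_over_6_5: 2
  inactive: 1
  active_minutes_met4_threshold: 40.0     # minutes/week at MET >= 4
  met_hours_fallback_threshold: 2.67      # MET-hours/week ~= 40 min at MET 4

bdsi:
  age_anchor: 65          # 0 age points at the lower design age
  design_age_range: [65, 79]
  education_under_12: 9
  bmi_under_18_5: 8
  diabetes: 3
  stroke: 6
  needs_help: 10
  depressive_symptoms: 6

anu_adri:
  # age-by-sex grid: 5-year bands from 65; values between the published
  # endpoints are a synthetic monotone interpolation (config-overridable)
  age_band_edges: [65, 70, 75, 80, 85, 90]
  age_points_male: [0, 6, 12, 18, 24, 30, 36]
  age_points_female: [0, 7, 14, 21, 28, 34, 41]
  education: {mid_min: 8, mid_max: 11, mid: 3, high: 6}   # as printed
  diabetes: 3
  head_trauma: 4
  depressive_symptoms: 2
  high_cholesterol: 3
  cholesterol_threshold: 6.5
  cognitive_activity: {low: 0, moderate: -6, high: -7}    # 'original' only
  pesticide_exposure: 2                                   # 'original' only
  social_engagement: {high: 0, medium_high: 1, medium_low: 4, low: 6}
  smoking: {never: 0, former: 1, current: 4}
  alcohol_light_moderate: -3
  physical_activity: {medium: -2, high: -3}
  activity_met_hours_medium: 30.0
  activity_met_hours_high: 90.0
  bmi_overweight: 2       # 25 <= BMI < 30
  bmi_obese: 5            # BMI >= 30
  fish: {"<=0.25": 0, "0.26-2.0": -3, "2.1-4.0": -4, ">=4.1": -5}

drs:
  deprivation_quintile_map: {0: 1, 1: 2, 2: 4, 3: 5}
  hypertension_sbp_threshold: 140.0
  young:
    age_band: "60-79"
    age_center: 65.608
    bmi_center: 27.501
    year_center: 2003.719
    baseline_survival: 0.9969
    coefficients:
      age: 0.20921
      age_sq: -0.00339
      bmi: -0.0616
      bmi_sq: 0.002508
      female: 0.12854
      hypertension: 0.13199
      calendar_year: 0.04477
      deprivation_q2: 0.013371
      deprivation_q3: 0.117904
      deprivation_q4: 0.201776
      deprivation_q5: 0.225529
      former_smoker: -0.06792
      current_smoker: -0.08657
      heavy_drinking: 0.443535
      depression_or_antidepressants: 0.833612
      aspirin: 0.252833
      stroke_or_tia: 0.577207
      atrial_fibrillation: 0.220728
      diabetes: 0.286701
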