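# Feature-category roll-up used by explanation summaries.
# Static features are listed explicitly; windowed features are assigned by
# their window suffix. Every schema feature must land in exactly one category.
static:
  device_information: [current_reading, time_of_day, day_of_week]
  demographics:
    [gender, diagnosis_age, prior_cgm_use, age, years_since_diagnosis, hba1c_latest]
window_suffixes:
  one_hour: short_term
  one_day: medium_term
  one_week: long_term
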