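# Recommendation templates keyed by target then by driver-feature base name
# (window suffix stripped). Placeholders: {feature}, {window}, {time_low},
# {time_high}, {time_in_range}, {peak_high_hour}, {peak_low_hour},
# {mean_glucose}. Phrasing is data, not code: edit freely.
# These sentences are illustrative interpretations of which feature drove
# risk, not medical advice.
hypo:
  current_reading: >-
    Predicted lows are driven mostly by the glucose level itself; low
    readings deserve prompt attention. Lows cluster around {peak_low_hour}:00.
  frac_time_low: >-
    Time spent low over the {window} window ({time_low:.1%} of readings this
    period) is the main driver of predicted lows; review basal/bolus settings.
  largest_decrease: >-
    Rapid single-step drops over the {window} window precede predicted lows;
    consider smaller correction doses.
  max_consec_dec: >-
    Sustained falling runs over the {window} window precede predicted lows;
    watch steep downward trends.
  sd_glucose: >-
    High glucose variability over the {window} window raises predicted low
    risk; steadier dosing and meals may help.
  mean_glucose: >-
    The {window} average glucose shapes predicted low risk (period mean
    {mean_glucose:.0f} mg/dL).
  generic: >-
    Predicted lows are most associated with '{feature}'; lows cluster around
    {peak_low_hour}:00.
hyper:
  current_reading: >-
    Predicted highs are driven mostly by the glucose level itself; highs
    cluster around {peak_high_hour}:00.
  frac_time_high: >-
    Time spent high over the {window} window ({time_high:.1%} of readings
    this period) drives predicted highs; this peaks around
    {peak_high_hour}:00, so review meal dosing near that time.
  largest_increase: >-
    Rapid rises over the {window} window precede predicted highs; consider
    earlier boluses around meals (highs peak near {peak_high_hour}:00).
  max_consec_inc: >-
    Sustained rising runs over the {window} window precede predicted highs;
    watch post-meal trends.
  sd_glucose: >-
    High variability over the {window} window raises predicted high risk.
  mean_glucose: >-
    The {window} average glucose shapes predicted high risk (period mean
    {mean_glucose:.0f} mg/dL).
  generic: >-
    Predicted highs are most associated with '{feature}'; highs cluster
    around {peak_high_hour}:00.
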