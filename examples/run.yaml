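# Canonical 24-h dual-hormone virtual trial on an inline synthetic cohort.
cohort_spec:
  n_patients: 15
  seed: 1
protocol:
  duration_days: 1
  start_time: "08:00"
  dosing_step_min: 10
  start_glucose: 7.0
  start_glucose_sd: 1.0
  carb_counting_error: true
  meals:
    - {name: breakfast, clock_time: "08:00", cho_g: 59, time_sd_min: 15, amount_sd_g: 5.9}
    - {name: lunch, clock_time: "12:00", cho_g: 70, time_sd_min: 15, amount_sd_g: 7.0}
    - {name: dinner, clock_time: "17:00", cho_g: 95, time_sd_min: 15, amount_sd_g: 9.5}
    - {name: snack, clock_time: "21:00", cho_g: 20, time_sd_min: 15, amount_sd_g: 2.0}
  arm: dual-hormone
  seed: 1
output_dir: trial_output
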