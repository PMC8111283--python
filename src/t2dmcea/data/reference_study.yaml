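model:
  start_age: 40
  n_cycles: 40
  cycle_length: 1.0
  discount_rate_cost: 0.03
  discount_rate_effect: 0.03
  half_cycle_correction: true
  recurrent_complication_events: false
  initial_state: controlled
event:
  cost: 228.0
  disutility: 0.13
disutilities:
  uncomplicated: 0.22
  complicated: 0.274
  death: 1.0
strategies:
- name: metformin_glibenclamide
  annual_treatment_cost: 75.0
  uncontrolled_treatment_cost: 208.0
  p_complication_controlled: 0.053
  p_complication_uncontrolled: 0.4
  p_failure: 0.06
- name: metformin_only
  annual_treatment_cost: 70.0
  uncontrolled_treatment_cost: 208.0
  p_complication_controlled: 0.122
  p_complication_uncontrolled: 0.4
  p_failure: 0.2
- name: metformin_saxagliptin
  annual_treatment_cost: 309.0
  uncontrolled_treatment_cost: 208.0
  p_complication_controlled: 0.013
  p_complication_uncontrolled: 0.4
  p_failure: 0.04
mortality:
  life_table: synthetic_life_table.csv
distributions:
- name: cost_metformin_glibenclamide
  family: gamma
  mean: 75.0
  sd: 7.5
  low: 60.0
  high: 90.0
- name: cost_metformin_saxagliptin
  family: gamma
  mean: 309.0
  sd: 30.9
  low: 247.2
  high: 370.8
- name: cost_metformin_only
  family: gamma
  mean: 70.0
  sd: 7.0
  low: 56.0
  high: 84.0
- name: cost_complication_event
  family: gamma
  mean: 228.0
  sd: 22.8
  low: 182.4
  high: 273.6
- name: cost_metformin_insulin
  family: gamma
  mean: 208.0
  sd: 20.8
  low: 166.4
  high: 249.6
- name: p_progression_glibenclamide
  family: beta
  mean: 0.053
  sd: 0.01
  low: 0.04
  high: 0.06
- name: p_progression_saxagliptin
  family: beta
  mean: 0.013
  sd: 0.0
  low: 0.01
  high: 0.03
- name: p_progression_metformin_only
  family: beta
  mean: 0.122
  sd: 0.01
  low: 0.1
  high: 0.15
- name: p_complication_insulin
  family: beta
  mean: 0.4
  sd: 0.04
  low: 0.32
  high: 0.48
- name: disutility_complicated
  family: beta
  mean: 0.274
  sd: 0.03
  low: 0.22
  high: 0.33
- name: disutility_uncomplicated
  family: beta
  mean: 0.22
  sd: 0.0
  low: null
  high: null
- name: event_disutility
  family: fixed
  mean: 0.13
  sd: 0.0
  low: null
  high: null
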