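# Base-case parameter set. Tables referenced at the bottom hold the
# age-band x gender values; entries tagged "fixture" in provenance are
# plausible stand-ins for values the cited sources do not print.
discount_rate: 0.03
cycle_length: 1.0
max_age: 110
retirement_age: 75
oa_progression_prob: 0.041
aseptic_to_infection_ratio_first: 6.69
aseptic_to_infection_ratio_second: 3.4
post_second_revision_utility_fraction: 0.90
oa_cost_offset: 590.0
recovery_missed_days: 40.0
first_year_indirect_fraction: 0.50
workdays_per_year: 250.0
medicare_to_all_payer_factor: 1.0
annual_tha_volume: 300000.0
initial_post_tha_blend: [0.25, 0.75]
perioperative_revision_mortality:
  lt75: 0.003
  ge75: 0.012
second_revision_rates:
  early/aseptic: 0.0583
  early/infection: 0.017
  late/aseptic: 0.022
  late/infection: 0.006
utilities:
  end_stage_oa: {M: 0.52, F: 0.47}
  nonsurgery: {M: 0.52, F: 0.47}
  more_severe_oa: 0.28
  initial_post_tha: 0.74
  successful_tha: {M: 0.83, F: 0.80}
  post_first_revision: 0.64
annual_costs:
  end_stage_oa: 12815.0
  initial_post_tha: 38965.0
  first_aseptic_revision: 57141.0
  first_infection_revision: 95763.0
provenance:
  discount_rate: published
  oa_progression_prob: published
  perioperative_revision_mortality: published
  second_revision_rates: published
  utilities: published
  annual_costs: published
  oa_cost_offset: published
  recovery_missed_days: published
  first_year_indirect_fraction: published
  retirement_age: published
  annual_tha_volume: published
  perioperative_tha_mortality: fixture
  first_revision_rates: fixture
  gender_weights: fixture
  age_band_weights: fixture
  workdays_per_year: fixture
  medicare_to_all_payer_factor: fixture
tables:
  perioperative_tha_mortality: tables/periop_tha_mortality.csv
  first_revision_rates: tables/first_revision_rates.csv
  gender_weights: tables/gender_weights.csv
  age_band_weights: tables/age_band_weights.csv
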