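# Simulated end-to-end run: a cyclone-prone coastal box with a true
# first-month effect of OR 1.5 injected into the cohort.
seed: 7
simulate:
  n_mothers: 6000
  children_per_mother_range: [2, 5]
  study_window: ["2004-01-01", "2014-12-31"]
  baseline_death_prob: 0.08
  true_or: 1.5
  n_storms: 12
  r34_range_km: [100.0, 300.0]
  storm_speed_kmh: 20.0
  bbox: [5.0, 15.0, 100.0, 110.0]
model:
  exposure_window: lag0
  spline_df: 6
stratifiers: [residence, sex]
sensitivity: true
burden: true
burden_years: [2012, 2013, 2014]
grid_spacing_km: 50.0
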