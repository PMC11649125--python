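# Demo pipeline configuration: 12×12 grid, 10 years, biweekly NDVI.
seed: 1
output_dir: results/demo
scenario:
  n_years: 10
  steps_per_month: 2
  grid_shape: [12, 12]
  gap_rate: 0.05
  outlier_rate: 0.02
iqr_k: 1.5
sg_window: 5
sg_order: 2
water_mode: pet
allocation_strategy: carbon_partition
daily_intake_p: 1800.0
grazing_days_t: 365.0
slope_threshold: 0.5
alpha: 0.05
cv_breaks: quantile
n_trees: 1000
rf_unit: pixel
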