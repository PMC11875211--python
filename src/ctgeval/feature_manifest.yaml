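# Canonical roster of the 44 segment descriptors, in output order.
# This file is the single source of truth for feature names and grouping;
# revise the roster here, not in code.
features:
  # -- baseline -------------------------------------------------------------
  - {name: baseline_bpm,                        group: baseline}
  - {name: baseline_drift_bpm_per_min,          group: baseline}
  - {name: bradycardia_fraction,                group: baseline}
  - {name: tachycardia_fraction,                group: baseline}
  # -- variability ----------------------------------------------------------
  - {name: short_term_variability_bpm,          group: variability}
  - {name: minute_range_mean_bpm,               group: variability}
  - {name: minute_range_median_bpm,             group: variability}
  - {name: minute_range_min_bpm,                group: variability}
  - {name: minute_range_max_bpm,                group: variability}
  - {name: low_variability_minutes_fraction,    group: variability}
  - {name: moderate_variability_minutes_fraction, group: variability}
  - {name: marked_variability_minutes_fraction, group: variability}
  # -- accelerations --------------------------------------------------------
  - {name: accel_count,                         group: acceleration}
  - {name: accel_total_duration_s,              group: acceleration}
  - {name: accel_mean_duration_s,               group: acceleration}
  - {name: accel_mean_amplitude_bpm,            group: acceleration}
  - {name: accel_max_amplitude_bpm,             group: acceleration}
  # -- decelerations, per type ----------------------------------------------
  - {name: early_decel_count,                   group: deceleration}
  - {name: early_decel_total_duration_s,        group: deceleration}
  - {name: early_decel_mean_depth_bpm,          group: deceleration}
  - {name: early_decel_mean_lag_s,              group: deceleration}
  - {name: late_decel_count,                    group: deceleration}
  - {name: late_decel_total_duration_s,         group: deceleration}
  - {name: late_decel_mean_depth_bpm,           group: deceleration}
  - {name: late_decel_mean_lag_s,               group: deceleration}
  - {name: variable_decel_count,                group: deceleration}
  - {name: variable_decel_total_duration_s,     group: deceleration}
  - {name: variable_decel_mean_depth_bpm,       group: deceleration}
  - {name: variable_decel_mean_lag_s,           group: deceleration}
  - {name: prolonged_decel_count,               group: deceleration}
  - {name: prolonged_decel_total_duration_s,    group: deceleration}
  - {name: prolonged_decel_mean_depth_bpm,      group: deceleration}
  - {name: prolonged_decel_mean_lag_s,          group: deceleration}
  # -- decelerations, aggregate ---------------------------------------------
  - {name: decel_count,                         group: deceleration}
  - {name: decel_total_duration_s,              group: deceleration}
  - {name: decel_max_depth_bpm,                 group: deceleration}
  # -- uterine contractions -------------------------------------------------
  - {name: uc_contraction_count,                group: uterine}
  - {name: uc_mean_interval_s,                  group: uterine}
  - {name: uc_mean_amplitude,                   group: uterine}
  - {name: decels_per_contraction,              group: uterine}
  # -- raw signal summary ---------------------------------------------------
  - {name: fhr_mean_bpm,                        group: signal}
  - {name: fhr_std_bpm,                         group: signal}
  - {name: fhr_min_bpm,                         group: signal}
  - {name: fhr_max_bpm,                         group: signal}
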