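# Condition parameter profiles, v1.
#
# Numbers encode in-vivo measurements on larval zebrafish Rohon-Beard sensory
# neurons (2-3 dpf) expressing GFP alone (WT), human wild-type alpha-synuclein
# (aSyn), or aSyn together with WldS or PGC-1alpha.  Where a quantity was not
# measured for a condition, the nearest measured condition's value is reused
# (see docs/methods.md for each such assumption).
#
# Unit conventions: speeds um/s, durations s, timing means/sds minutes,
# density per 100 um of axon, probabilities in [0, 1].
schema_version: 1
conditions:
  WT:
    transport:
      motile_fraction: 0.274            # percent motile 27.4%
      anterograde_run_speed_mean: 0.56  # um/s, uninterrupted runs
      anterograde_run_speed_sd: 0.21
      retrograde_run_speed_mean: 0.57
      retrograde_run_speed_sd: 0.25
      mean_run_duration: 8.0
      mean_pause_duration: 5.617        # = 8.0 * 0.4125 / 0.5875
      prob_next_run_retrograde: 0.3797  # retrograde share of moving time 22.31/58.75
      target_time_fraction_paused: 0.4125
    morphology:
      density_per_100um: 22.6
      aspect_ratio_mean: 2.01           # length:width
      aspect_ratio_sd: 0.80
      mito_minor_axis_um: 0.7
      swollen_fraction: 0.05
    axonopathy:
      # 2-dpf stages: 11/12 smooth (stage 1), 1/12 mild beading (stage 2)
      stage_probabilities_at_2dpf: [0.91667, 0.08333, 0.0, 0.0, 0.0]
      stage_transition_matrix_per_day:
        - [0.95, 0.04, 0.01, 0.00, 0.00]
        - [0.00, 0.90, 0.10, 0.00, 0.00]
        - [0.00, 0.00, 0.90, 0.10, 0.00]
        - [0.00, 0.00, 0.00, 0.90, 0.10]
        - [0.00, 0.00, 0.00, 0.00, 1.00]
      death_given_stage5: 1.0
    timing:
      lag_mean: 129.1                   # transection -> fragmentation, minutes
      lag_sd: 33.2                      # sd = sem 10.0 * sqrt(n=11)
      clearance_mean: 58.2
      clearance_sd: 22.9
      axonopathy_onset_lead_hours: 4.0
      sampling_interval: 30.0
    survival_2to3dpf: 1.0
    new_expression_rate: 0.029          # net 3-dpf count 102.9% of 2-dpf count
  aSyn:
    transport:
      motile_fraction: 0.1505
      anterograde_run_speed_mean: 0.53
      anterograde_run_speed_sd: 0.31
      retrograde_run_speed_mean: 0.64
      retrograde_run_speed_sd: 0.30
      mean_run_duration: 8.0
      mean_pause_duration: 9.707        # = 8.0 * 0.5482 / 0.4518
      prob_next_run_retrograde: 0.6151  # retrograde share of moving time 27.79/45.18
      target_time_fraction_paused: 0.5482
    morphology:
      density_per_100um: 30.2
      aspect_ratio_mean: 1.48
      aspect_ratio_sd: 0.37
      mito_minor_axis_um: 0.9
      swollen_fraction: 0.30
    axonopathy:
      # 2-dpf stages: 3/19 stage 1, 12/19 stage 2, 4/19 stage 3
      stage_probabilities_at_2dpf: [0.158, 0.632, 0.210, 0.0, 0.0]
      stage_transition_matrix_per_day:
        - [0.667, 0.333, 0.00, 0.00, 0.00]
        - [0.000, 0.710, 0.10, 0.05, 0.14]
        - [0.000, 0.000, 0.45, 0.20, 0.35]
        - [0.000, 0.000, 0.00, 0.30, 0.70]
        - [0.000, 0.000, 0.00, 0.00, 1.00]
      death_given_stage5: 0.58
    timing:
      lag_mean: 112.7
      lag_sd: 45.3                      # sd = sem 11.7 * sqrt(n=15)
      clearance_mean: 69.1
      clearance_sd: 32.1
      axonopathy_onset_lead_hours: 4.0
      sampling_interval: 30.0
    survival_2to3dpf: 0.817
    new_expression_rate: 0.0
  aSyn+WldS:
    # transport/morphology not measured for this condition; aSyn values reused
    transport:
      motile_fraction: 0.1505
      anterograde_run_speed_mean: 0.53
      anterograde_run_speed_sd: 0.31
      retrograde_run_speed_mean: 0.64
      retrograde_run_speed_sd: 0.30
      mean_run_duration: 8.0
      mean_pause_duration: 9.707
      prob_next_run_retrograde: 0.6151
      target_time_fraction_paused: 0.5482
    morphology:
      density_per_100um: 30.2
      aspect_ratio_mean: 1.48
      aspect_ratio_sd: 0.37
      mito_minor_axis_um: 0.9
      swollen_fraction: 0.30
    axonopathy:
      # 2-dpf mean stage 1.57 (moderate axon protection)
      stage_probabilities_at_2dpf: [0.54, 0.36, 0.09, 0.01, 0.0]
      stage_transition_matrix_per_day:
        - [0.75, 0.25, 0.00, 0.00, 0.00]
        - [0.00, 0.72, 0.10, 0.04, 0.14]
        - [0.00, 0.00, 0.50, 0.20, 0.30]
        - [0.00, 0.00, 0.00, 0.30, 0.70]
        - [0.00, 0.00, 0.00, 0.00, 1.00]
      death_given_stage5: 0.60
    timing:
      lag_mean: 400.0                   # WldS delays injury-induced fragmentation
      lag_sd: 60.0
      clearance_mean: 58.2
      clearance_sd: 22.9
      axonopathy_onset_lead_hours: 4.0
      sampling_interval: 30.0
    survival_2to3dpf: 0.869
    new_expression_rate: 0.0
  aSyn+PGC1a:
    # PGC-1alpha restores transport/morphology; WT values reused
    transport:
      motile_fraction: 0.274
      anterograde_run_speed_mean: 0.56
      anterograde_run_speed_sd: 0.21
      retrograde_run_speed_mean: 0.57
      retrograde_run_speed_sd: 0.25
      mean_run_duration: 8.0
      mean_pause_duration: 5.617
      prob_next_run_retrograde: 0.3797
      target_time_fraction_paused: 0.4125
    morphology:
      density_per_100um: 22.6
      aspect_ratio_mean: 2.01
      aspect_ratio_sd: 0.80
      mito_minor_axis_um: 0.7
      swollen_fraction: 0.05
    axonopathy:
      # 2-dpf mean stage 1.07 (near-complete protection)
      stage_probabilities_at_2dpf: [0.93, 0.07, 0.0, 0.0, 0.0]
      stage_transition_matrix_per_day:
        - [0.930, 0.050, 0.010, 0.005, 0.005]
        - [0.000, 0.900, 0.080, 0.010, 0.010]
        - [0.000, 0.000, 0.900, 0.050, 0.050]
        - [0.000, 0.000, 0.000, 0.900, 0.100]
        - [0.000, 0.000, 0.000, 0.000, 1.000]
      death_given_stage5: 1.0
    timing:
      lag_mean: 129.1
      lag_sd: 33.2
      clearance_mean: 58.2
      clearance_sd: 22.9
      axonopathy_onset_lead_hours: 4.0
      sampling_interval: 30.0
    survival_2to3dpf: 0.986
    new_expression_rate: 0.0
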