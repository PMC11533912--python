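# Calibrated study-condition presets used by `tapdose simulate --preset study`
# and `tapdose report`.  These are the defaults of the synthetic-data module
# spelled out for reproducibility; override any key with a user YAML.
biodist:
  peptide_masses_ng: [28, 140, 280]
  noise_cv: 0.10
  n_per_timepoint: 5
  timepoints_h: [1.0, 4.0, 24.0]
  half_life_h: 10.64
binding:
  kd_nm: 3.93
  bmax: 20000
  ns_fraction: 0.05
  cv: 0.05
  concentrations_nm: [0.5, 1, 2, 4, 8, 16, 32, 64]
  n_replicates: 3
survival:
  study_end_weeks: 28.0
  shape: 2.5
  median_weeks:
    control_buffer: [9.4, 10]
    control_irrelevant: [10.5, 10]
    treated_4x370kBq: [18.9, 15]
    treated_3x555kBq: [16.0, 15]
    treated_1x1665kBq: [14.7, 15]
chromatogram:
  main_area_fraction: 0.96
  total_counts: 100000
dose:
  rbe: 5.0
  photon_absorbed_fraction: 0.0
  activities_gbq: [0.111, 0.555, 1.110]
  mouse_phantom: mouse_female
  human_phantom: human_female
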