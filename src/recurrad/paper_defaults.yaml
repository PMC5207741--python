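# Study-scale default configuration: a 112-subject cohort with ~20% DM
# events, a 31-subject test-retest arm, and the published analysis
# thresholds. Hazard is tied to AIP morphology (volume, cluster shade);
# per-subject respiratory amplitude (2-18 mm) shapes the AIP but is
# invisible to the static FB snapshot, so FB sees the signal attenuated.
seed: 0
n_subjects: 112
n_retest_subjects: 31
radius_jitter: 0.15
motion_amplitude_mm: 10.0
motion_amplitude_range: [2.0, 18.0]
motion_phases: 10
reimage_shift_mm: 1.0
reimage_noise_sd: 5.0
phantom:
  grid_shape: [64, 64, 64]
  spacing: [1.0, 1.0, 1.0]
  tumor_radii: [12.0, 10.0, 11.0]
  lobulation_amplitude: 0.15
  texture_sd: 40.0
  noise_sd: 10.0
outcome_signal_dm:
  Volume: 0.5
  "Wv LLL GLCM clusShade": 0.6
outcome_signal_lrr: {}
baseline_rate: 0.0095
censor_rate: 0.03
max_followup: 48.0
thresholds:
  icc: 0.8
  pca_variance: 0.95
  score_correlation: 0.99
  spearman: 0.8
  fdr: 0.05
n_splits: 100
n_permutation: 200
registry_fb: table2_fb
registry_aip: table2_aip
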