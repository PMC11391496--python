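# Example pipeline configuration (all keys optional; defaults shown).
# Unknown keys are rejected.

output_dir: vfnet_out
simulate: true        # generate a synthetic cohort; false requires cohort_dir
cohort_dir: null      # directory written by `vfnet simulate`
seed: 0               # master seed; every stage derives its streams from it

# denoising
low_hz: 0.009         # band-pass lower edge (Hz)
high_hz: 0.10         # band-pass upper edge (Hz)
z_thresh: 5.0         # outlier frame: |global-signal z| threshold
motion_thresh_mm: 0.9 # outlier frame: framewise motion differential (mm)

# graph metrics (proportional thresholding)
density_min: 0.05
density_max: 0.40
density_step: 0.01

# community detection / affinity
community_runs: 100   # stochastic modularity optimisations per subject
gamma: 1.0            # modularity resolution
community_cortices: [left-frontal, left-temporal]

# statistics
alpha: 0.05
covariates: [age, sex, education, moca]

# laterality index
li_mask: frontal      # cortex-label substring pooled over both hemispheres
li_threshold: 2.0     # suprathreshold t cutoff

# classification (sclerosis-like vs non-sclerosis-like groups)
classify_groups: [TLE-HS, TLE-NHS]
p_enter: 0.05         # stepwise entry p-value
hidden_units: 4
train_frac: 0.7
repetitions: 100
max_classifier_features: 30

# stage toggles
with_community: true
with_classification: true

# synthetic cohort generator overrides (flat mapping of generator fields)
cohort:
  group_sizes: {HC: 29, TLE-HS: 30, TLE-NHS: 28}
  effect_map:
    TLE-HS: {L_aITG: -0.15}
    TLE-NHS: {L_aITG: 0.10}
  within_cortex_r: 0.4
  between_cortex_r: 0.1
  subject_conn_sd: 0.05
  ar_coef: 0.4
  noise_sd: 0.4
  drift_amplitude: 0.3
  task_amplitude: 0.6
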