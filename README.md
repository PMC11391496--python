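# vfnet

ROI-level task-fMRI network analysis of Chinese verbal-fluency circuits
in temporal lobe epilepsy (TLE), for researchers who want a tested,
reproducible re-implementation of the full analysis chain — and a
synthetic cohort generator to exercise it end-to-end without any data
download.

The package models a three-group design (healthy controls, TLE with
hippocampal sclerosis, TLE without) observed through a block-design
covert word-generation task (five blocks of 30 s rest / 30 s task,
TR = 1 s) on a 132-region parcellation, and implements:

- **Denoising** — outlier-frame detection, confound regression (motion,
  spikes, task effect, nuisance signals), zero-phase 0.009–0.10 Hz
  band-pass.
- **Functional connectivity** — per-subject 132×132 Pearson matrices and
  the 771 Fisher-z edge features seeding from six left frontal/temporal
  ROIs.
- **Degree centrality (DC)** — proportional thresholding at densities
  5–40% (step 1%), degree curves, and their area under the curve:
  AUC_i = ∫ DC_i(d) dd.
- **Community affinity** — Newman–Girvan weighted modularity
  Q = (1/2m) Σ_ij [W_ij − γ k_i k_j/2m] δ(c_i, c_j), optimised by a
  stochastic Louvain-style algorithm, 100 runs per subject; the affinity
  of region i to cortex X is A_iX = (1/n_Xi) Σ_{j∈X, j≠i} P_ij with P_ij
  the co-assignment probability across runs.
- **Task GLM / laterality** — per-region block-design GLM betas and the
  frontal laterality index LI = (L−R)/(L+R) with the ±0.2 dominance rule.
- **Group statistics** — one-way ANCOVA (covariates age, sex, education,
  MoCA) with post hoc contrasts and Benjamini–Hochberg FDR at α = 0.05,
  HC-standardised scores, partial correlations.
- **Classification** — forward stepwise logistic selection (likelihood-
  ratio entry, p < 0.05) feeding a single-hidden-layer tanh/softmax
  network trained by scaled conjugate gradient (initial λ = 5e-7,
  initial σ = 5e-5, weights ~ U[−0.5, 0.5]), evaluated by 100 stratified
  70/30 splits and rank-based ROC AUC.

The classifiers are scikit-learn estimators (`ForwardStepwiseLogistic`,
`ScgMlpClassifier`, `StepwiseNN`) and compose with sklearn model
selection; the synthetic generator is first-class, tested code.

## Worked example

Run the whole pipeline on a simulated default cohort (87 subjects:
29 HC, 30 TLE-HS-like, 28 TLE-NHS-like):

```python
from vfnet import PipelineConfig, run_pipeline

res = run_pipeline(PipelineConfig(output_dir="vfnet_out", seed=7))
s = res["summary"]
print("subjects:", s["n_subjects"], "| edge features:", s["n_edge_features"])
print("significant edges:", s["significant_edges"],
      "| significant DC-AUC:", s["significant_dc_auc"])
c = s["classification"]
print("selected features:", c["selected_features"])
print("logistic in-sample AUC: %.3f" % c["logistic_insample_auc"])
print("NN 70/30 x %d mean AUC: %.3f" % (c["repetitions"], c["nn_split_mean_auc"]))
```

prints

```
subjects: 87 | edge features: 771
significant edges: 131 | significant DC-AUC: 1
selected features: ['vfc', 'L_aITG~midline-other_03']
logistic in-sample AUC: 1.000
NN 70/30 x 100 mean AUC: 0.966
```

Reading the output: the generator injects a connectivity deficit on the
seed region (the left anterior inferior temporal gyrus analogue,
`L_aITG`) in the sclerosis-like group and an enhancement in the
non-sclerosis-like group, so the edges that survive FDR are almost all
`L_aITG` edges (131 of 771), the seed's DC-AUC differs between groups,
and the classifier separates the two patient groups nearly perfectly —
the in-sample logistic AUC of 1.0 illustrates why only the split-based
estimate (0.966) should be trusted. The top surviving edges, from
`vfnet_out/stats_edges.csv`:

```
                               F    p    q
L_aITG~right-frontal_07  35.6866  0.0  0.0
L_aITG~right-frontal_18  30.6483  0.0  0.0
L_aITG~left-frontal_07   29.8347  0.0  0.0
```

The same run is available from the shell, plus per-stage subcommands:

```bash
vfnet run --simulate --seed 7 --out vfnet_out
vfnet simulate --out cohort_dir --seed 7      # write a cohort as TSV/CSV
vfnet prep sub-000_timeseries.tsv sub-000_motion.tsv --out clean.tsv
vfnet connectivity clean.tsv --out matrix.tsv
vfnet stats edge_features.csv subjects.csv --out stats.csv --alpha 0.05
vfnet classify edge_features.csv subjects.csv --out report.json --reps 100
```

All outputs are plain text (TSV/CSV/JSON) with a `# key: value`
provenance header; two runs with the same seed produce byte-identical
bundles. A fully documented configuration file is at
`docs/example-config.yaml`; the scientific details and all modelling
choices are in `docs/methods.md`.

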