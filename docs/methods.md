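# Methods

`vfnet` re-implements, at ROI level, a task-fMRI network analysis of
verbal-fluency circuits in temporal lobe epilepsy (TLE): per-subject
functional connectivity from a block-design covert word-generation task,
degree-centrality curves over proportional thresholds, consensus-community
affinity, covariate-adjusted group statistics with FDR control, and a
two-stage classifier separating patients with and without hippocampal
sclerosis. Because no subject-level data are deposited for this design,
the package ships a synthetic cohort generator that reproduces the
statistical structure the analysis assumes; every downstream stage is
exercised and validated on generated cohorts.

## The synthetic cohort generator

The generator emulates a three-group cross-sectional study — 29 healthy
controls (HC), 30 patients with hippocampal sclerosis (TLE-HS), and 28
without (TLE-NHS) — observed through a 132-region parcellation analogue
(four 20-region frontal/temporal blocks, 11 midline cortical, 15
subcortical, 26 cerebellar regions; six left frontal/temporal regions are
flagged as ROIs, with the left anterior inferior temporal gyrus analogue
`L_aITG` acting as the seed of the group effect).

Per subject the signal model is, in order:

1. **Target correlation structure.** A block matrix (within-cortex r = 0.4,
   between-cortex r = 0.1) gives community detection a planted ground
   truth. The group effect adds a signed offset to every edge of the seed
   region: −0.15 for TLE-HS-like subjects (impaired seed connectivity)
   and +0.10 for TLE-NHS-like subjects (enhancement), plus a subject-level
   jitter (SD 0.05) so that connectivity varies within group and
   behavioural scores can correlate with it. The offsets are free
   parameters: the study design they emulate reports significance, not
   effect sizes, so the defaults were fixed once at values that give the
   three-group contrast a clearly detectable but not degenerate effect
   (Fisher-z group contrasts of roughly 0.2–0.3 at T = 300).
   If the offsets break positive semi-definiteness, the matrix is
   repaired by clipping eigenvalues at 1e-6 and rescaling to unit
   diagonal (simplest deterministic fix; logged).
2. **Temporal structure.** Latent innovations drawn from the target
   Gaussian are smoothed by a unit-variance AR(1) recursion (coefficient
   0.4), preserving cross-correlations while giving BOLD-like temporal
   autocorrelation.
3. **Task response.** The paradigm is five blocks of 30 s rest then 30 s
   task at TR = 1 s (300 timepoints). The expected response is the task
   boxcar convolved with a canonical double-gamma HRF (peak 6 s,
   undershoot 16 s, ratio 6 — the standard parameterisation; the source
   analysis delegates this to its first-level software and never states
   it), scaled by 0.6 in left frontal/temporal regions and 0 elsewhere.
4. **Nuisance.** A slow cosine drift (amplitude 0.3, random phase), white
   observation noise (SD 0.4), six rigid-body motion traces (random walks
   with Poisson-rate spike frames, the ground truth for outlier
   detection), and two noise channels standing in for white-matter/CSF
   averages.

Covariates (age, sex, education, MoCA) are drawn from plausible
distributions with a slightly lower MoCA mean in the patient groups;
verbal-fluency scores (character/Pinyin/semantic: VFC, VFP, VFS) are
linear in the subject's target seed-region mean connectivity plus noise,
so score–connectivity correlations exist by construction.

All randomness flows from a single master seed through spawned
`SeedSequence` streams (one per subject, plus per-stage derivations in
the pipeline), so identical configurations reproduce byte-identical
cohorts and result bundles.

**What the generator does not emulate:** volumetric data and spatial
preprocessing, physiological (cardiac/respiratory) noise, realistic
motion-artefact coupling into the signal, non-Gaussian BOLD amplitude
distributions, site/scanner effects, and any asymmetry in task response
between groups. Passing tests therefore demonstrate correctness of the
*analysis machinery* under the assumed statistical structure, not
robustness to real acquisition artefacts.

## Denoising

The ROI-level analogue of the connectivity-toolbox chain: a frame is an
outlier when its global-signal z-score exceeds 5 or the framewise motion
differential exceeds 0.9 mm (conventional intermediate thresholds — the
source names the detection tool but not its settings); outlier frames
become one-hot spike regressors (regression rather than deletion keeps
timepoints aligned for filtering); the confound design is
[motion | spikes | task HRF + temporal derivative | nuisance channels]
plus an intercept, removed by OLS per region; then a zero-phase
(forward–backward) Butterworth band-pass of order 2 keeps
0.009–0.10 Hz. Collinear confound columns are dropped with a warning
rather than failing.

Numerical notes: OLS residuals are exactly orthogonal to every confound
column (re-regression is a no-op to < 1e-8), but the full chain is not
exactly idempotent — any realisable IIR band-pass has passband gain
slightly below 1 near the band edges, so filtering twice attenuates
edge-frequency content, and outlier re-detection on cleaned data can
flag different frames. The activation (GLM) stream deliberately skips
the task regressor and the band-pass: removing the task effect is
correct when estimating task-independent connectivity but would null
the very activations the GLM estimates.

## Connectivity and edge features

Functional connectivity is the Pearson correlation between two regions'
denoised series (diagonal set to 0; constant regions get zeroed rows
with a warning; raw series are refused via a provenance flag). The group
comparison operates on Fisher-z transformed correlations between each of
the six ROIs and every other region: 6 × 131 ordered pairs minus the
C(6,2) = 15 duplicate ROI–ROI pairs (kept once, in canonical
orientation) gives 771 edge features.

## Degree centrality and its AUC

Each weighted matrix is binarised at connection densities 5–40% in steps
of 1% by keeping the k = round(d·M) highest-weight edges of the
M = n(n−1)/2 pairs (signed ranking — strong negative correlations are
never "connections"; a magnitude option exists), with half-up rounding
and lexicographic tie-breaking, so edge sets are nested and degree curves
non-decreasing. Degree centrality is the row sum of the binary adjacency;
the summary is the trapezoidal area under the degree-vs-density curve
(a step-sum mode is available for sensitivity; neither the rounding nor
the quadrature is stated by the source, both are documented choices).
Edges are ranked over the whole network by default.

## Community structure and affinity

Connectivity among the left frontal + temporal regions is extracted,
negative weights are zeroed (a signed-modularity treatment is out of
scope), and communities are found by maximising Newman–Girvan weighted
modularity

Q = (1/2m) Σ_ij [W_ij − γ k_i k_j / 2m] δ(c_i, c_j),  γ = 1 by default,

with a Louvain-style greedy two-phase algorithm: local moves in
seed-shuffled node order (ties keep the current community; a fresh
singleton community is always an available move target), aggregation,
and — beyond the textbook version — repeated two-phase cycles that
restart node-level moves from the current partition until Q stops
improving (gain < 1e-10). This refinement is deterministic given the
seed, never decreases Q, and measurably raises the frequency of reaching
the global optimum on small graphs above that of the reference igraph
implementation.

Because the optimisation is stochastic, it is repeated 100 times per
subject; the co-assignment matrix P_ij is the fraction of runs placing
regions i and j in the same community, and the affinity of region i to
cortex X is the mean of P_ij over the members of X other than i. On a
planted two-block network (within 0.4, between 0.05) every node's
own-block affinity is ~1 and cross-block ~0. The source's exact quality
function and resolution are not printed, so only structural behaviour —
not particular Q values — can be asserted.

## Task GLM and laterality

Per region, OLS of the signal on [task regressor | cosine drifts |
intercept] yields the task beta and t (residual dof, two-sided p). The
laterality index over a cortical mask (frontal by default) is
LI = (L − R)/(L + R) on sums of suprathreshold (t > 2) positive t-mass
per hemisphere; dominance is left for LI > 0.2, right for LI < −0.2,
bilateral otherwise, and a zero-mass case returns a flagged bilateral
result. This fixed-threshold mass formula is a documented divergence
from voxel-based bootstrap LI tools, which need voxel data that are out
of scope here.

## Group statistics

Every feature family (771 edges; DC-AUC of the 6 ROIs; 12 affinities;
132 activation betas) is tested by one-way ANCOVA — feature ~ group +
age + sex + education + MoCA — via vectorised full-vs-reduced OLS
F-tests (exactly one-way ANOVA when covariates are empty; a feature with
no residual variation is reported F = 0, p = 1 by convention). Post hoc
pairwise contrasts of adjusted means use the full-model residual dof and
are computed, by default, only for features whose omnibus q survives
Benjamini–Hochberg FDR at α = 0.05 within their family; pairwise
p-values are BH-corrected across the surviving features per pair.
Rejection is q < α; SDs use the n−1 denominator throughout. Behavioural
scores are z-standardised against the HC group, and partial correlations
(Pearson on OLS residuals, t at n − 2 − k dof) relate them to each other
and to significant edges.

Null calibration (independent-region cohorts, 87 subjects) puts the
realised mean false-discovery proportion at ~0.04–0.05; with the
block-correlated default structure BH's guarantee degrades mildly
(~0.065 measured), the known behaviour under general dependence.

## Classification

To separate TLE-HS-like from TLE-NHS-like subjects, candidate features
(FDR-surviving functional statistics, capped at the 30 smallest-q for
per-split tractability, plus the three fluency scores) enter a forward
stepwise logistic regression: at each step the candidate with the
smallest likelihood-ratio entry p is added while p < 0.05 (a Rao score
test mode is available; the original software's entry statistic is not
recoverable). Fitting is IRLS to tolerance 1e-8 with perfect-separation
detection (coefficients kept from the last stable iteration, flagged).
The selected features feed a single-hidden-layer feed-forward network
(tanh hidden units, default 4 — the original auto-selects its size —
softmax output) trained by scaled conjugate gradient on cross-entropy
with initial lambda 5e-7, initial sigma 5e-5, and weights initialised
uniformly on [−0.5, 0.5]; a zero initialisation interval cannot break
hidden-unit symmetry and is warned about.

Generalisation is estimated by 100 stratified 70/30 train/test splits:
selection and training happen strictly inside each training split, the
held-out part is scored by rank-based ROC AUC (ties ½), and the summary
is the mean with a percentile 95% interval. In-sample AUC of the
full-sample logistic fit is reported separately and is near 1 by
construction on separable data — only the split-based estimate is
meaningful for validation. The unregularised network memorises separable
training sets, so split AUC saturates only when the group separation is
strong (two ±4 SD features give mean AUC ≈ 0.99; a single 3-SD feature
gives ≈ 0.95).

## Problem sizes used in validation

The test-suite and acceptance computations run at sizes chosen to keep a
full validation pass to a few minutes while preserving each check's
power: the end-to-end pipeline at the full default design (87 subjects ×
132 regions × 300 timepoints, 100 community runs, 100 splits); Louvain
vs exhaustive enumeration on 200 sparse Erdős–Rényi graphs of 4–8 nodes
(Bell-number enumeration bounds the size); FDR calibration on 2,000
null cohorts of 10 regions; effect-size recovery (a Fisher-z ≈ 0.3
seed deficit, edge offset −0.28) on 100 cohorts of 12 regions at the
full n = (29, 30, 28).

## Known limitations

- Synthetic validation only: no real-data ingestion beyond the package's
  own text formats (an adapter point for NIfTI/atlas input is left at
  `RoiTimeSeries`).
- Louvain-style greedy optimisation does not guarantee the global
  modularity optimum (measured ~94–98% on small random graphs,
  ensemble-dependent); consensus over 100 runs is the mitigation.
- BH-FDR's mean-FDP control degrades slightly under strong positive
  dependence among edge features.
- The fixed-threshold LI departs from bootstrap voxel-count LI tools.
- The hidden-layer width and entry-test variant of the original
  classifier are not recoverable; both are configurable.
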