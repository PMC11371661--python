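# Methods

This note records the model and procedure implemented by `scfc`, the
conventions and numerical choices that were genuinely open, and what the
synthetic test bed does and does not establish about real data.

## Network construction and thresholding

Functional connectivity is the absolute Pearson correlation of
region-averaged time series (`network.build_fc`; the absolute-value step is
a flag, default on, because signed-FC thresholding is a live convention
choice in the field). Structural connectivity is any nonnegative
edge-weight matrix; direction-dependent tractography outputs are averaged
with their transpose (`network.symmetrize_sc`). Because the coupling
statistic is a Pearson correlation, it is invariant to positive affine
rescaling of SC, so waytotal-normalized and raw connection counts give
identical coupling (tested).

Proportional thresholding keeps exactly `round_half_away(s·n(n−1)/2)`
upper-triangle edges at sparsity `s`. Ties at the cut are broken by
ascending (row, col) index — an arbitrary but deterministic rule that makes
the threshold series *nested*: the retained set at a lower sparsity is a
subset of the set at any higher sparsity. The default series is 8%–60% in
2% steps (27 levels); both endpoints and step are configurable.

## Coupling

At each sparsity, coupling is the Pearson correlation between surviving FC
weights and the corresponding SC weights, over all retained edges (whole
brain) or the retained edges with both endpoints in one module. SC zeros
are included as ordinary values — no structural-edge filtering — since the
statistic is defined on the functional edge set. A scope with fewer than
three surviving edges, or zero variance in either vector, yields an
undefined (NaN) value.

The AUC summary is the trapezoidal integral of the per-threshold curve
divided by the threshold range. Normalizing by the range keeps the summary
on the metric's own scale (a constant curve summarizes to the constant),
which is what makes per-threshold values and AUC values comparable in the
same table. Up to 10% undefined points per scope are filled by linear
interpolation between defined neighbours (nearest value at the ends); more
missingness leaves the AUC undefined rather than silently extrapolated.
Coupling r values enter group statistics untransformed; Fisher-z is left to
the caller because the group models operate on the metrics directly.

## Graph metrics

Weighted-network conventions: weights are divided by the matrix maximum, edge
lengths are reciprocal normalized weights, distances come from Dijkstra
(`scipy.sparse.csgraph`), and efficiencies are means of inverse distances
with disconnected pairs contributing zero. This bounds E_glob, E_loc and
E_nodal in [0, 1] and keeps them finite and monotone at sparse thresholds.
Local efficiency of a node is the global efficiency of the subgraph induced
by its neighbours, with weights kept on the parent's normalized scale
(no re-normalization inside the subgraph); nodes with fewer than two
neighbours contribute zero. L_p defaults to the harmonic convention
1/E_glob, which is defined whenever any pair is connected; an arithmetic
convention (mean of finite distances) is available because toolboxes differ
and the choice matters exactly when networks fragment. The convention in
force is recorded in the results metadata.

## Inference

ANCOVA is an OLS fit of `metric ~ group dummies + covariates` (reference
level = last group, i.e. controls; sex enters as a single binary dummy).
The omnibus test is the partial F comparing against the covariate-only
model; pairwise comparisons are unadjusted model contrasts — the
least-significant-difference convention extended to the covariate-adjusted
model — and adjusted means are predictions at the grand covariate means.
With no covariates this reduces exactly (to 1e-10, tested) to one-way ANOVA
plus LSD. The summary-statistic ANOVA form (`anova_oneway_summary`)
reconstructs the same F from per-group (n, mean, sd), which is what lets
published demographic tables be recomputed.

Partial correlation residualizes both variables on [intercept, covariates]
and tests t = r·sqrt(df/(1−r²)) on df = n−2−c, complete cases only.
FDR control is Benjamini–Hochberg, applied within one group's
metric×score family; both raw p and q are reported because the appropriate
family is a judgment call. Note that BH adjusted values are *not* a fixed
point of the procedure — re-adjusting q-values changes them — so only the
single application is meaningful.

K–S normality testing uses estimated parameters, whose naive p-value is
anticonservative; the primary p-value therefore comes from a seeded
Monte-Carlo null (10,000 standard-normal samples re-tested against their own
estimated parameters, Lilliefors-style), with the naive p reported alongside
for auditability.

## Synthetic cohort generator

The generator produces, per subject, a structural matrix, a coupled
functional matrix, covariates and cognitive scores. It emulates a
three-group CSVD study: 54 severe, 106 mild, 79 control subjects on a
90-region parcellation with five modules (20/14/18/18/20 regions),
whole-brain coupling targets 0.268/0.278/0.284 and module targets of the
same order, age ~ N(62, 8²) yr, education ~ N(12, 3.3²) yr, sex ~
Bernoulli(0.55), head motion ~ N(0.12, 0.04²) mm truncated at 0.01.

Structure is generated at the edge level, not from a biophysical model,
because the analysis only assumes a monotone edge-wise FC–SC association:

* SC edges are log-normal (σ = 0.4) with a +0.5 log-location bonus inside
  modules (modular block structure).
* Within each edge group (each module's internal edges; all between-module
  edges as one group) SC is rank-normalized to z, a latent functional value
  is mixed as `a·z + sqrt(1−a²)·noise_sd·ε`, and the latent value is
  squashed to an absolute-correlation-like weight
  `|tanh(0.35·(latent + 1.5 + 0.4·within_module + efficiency_shift))|`.
  The tanh-with-offset map plays the role of the absolute-FC convention
  while remaining effectively monotone over the latent's realized range.

**Calibration.** Proportional thresholding restricts the coupling estimator
to the strongest FC edges, which attenuates the edge-level correlation: at
mid-range the measured coupling AUC is roughly 0.6× the latent mixing
weight, and the whole-brain statistic additionally pools edge groups whose
block structure alone contributes a baseline (~0.05) and a ceiling (~0.77).
So that a requested target is what the estimator actually recovers, the
generator inverts a frozen calibration curve (one for within-module groups,
one for the pooled whole-brain scope) measured once at the default settings
(90 regions, default partition and threshold scheme, noise_sd = 1) and
stored as an interpolation table in `simulate.py`. The inversion is exact
mid-range (mean absolute error ~0.02 on a 0.1–0.9 grid) and clamps outside
the attainable range; it is approximate for non-default schemes or SC
distributions, where targets should be read as ordinal.

Subject heterogeneity is a shared N(0, 0.02²) offset added to all of a
subject's targets; combined with ~0.025 estimation noise this reproduces the
emulated regime's between-subject sd (~0.03) of the whole-brain coupling
AUC. Cognitive scores are linear in the subject's true whole-brain target
plus covariate effects and residual noise, with slopes set so the
coupling↔score partial correlations land near |r| ≈ 0.3. Optional BOLD-like
time series are drawn from a zero-mean Gaussian whose correlation matrix is
the nearest valid correlation matrix to the FC target (alternating
eigenvalue clipping at 1e-8 and unit-diagonal renormalization, tolerance
1e-10, ≤200 iterations) — note an arbitrary all-positive FC matrix is
generally far from PSD, so the series reproduce the projection, not the raw
target.

**What the generator does not emulate:** hemodynamics, spatial
autocorrelation, distance-dependent connectivity, lesion topography,
negative-correlation structure, site/scanner effects, or missing data
mechanisms beyond missing-at-random scores. Passing tests therefore
establish correctness of the *estimators and inference* under a controlled
monotone edge-wise coupling model, not robustness to real-data artifacts.

## Problem sizes and determinism

A single RNG stream seeded from the config drives each cohort, so equal
seeds give byte-identical outputs (tested end to end). The test suite runs
its heavier simulations at deliberately modest sizes — e.g. 200 brute-force
oracle networks of ≤10 nodes, 20 seeds per point for parameter recovery,
2000 simulated nulls for type-I calibration, and a handful of full-size
cohort replicates for the group-signature check — sizes at which every
stochastic assertion was verified stable under its fixed seeds. The
acceptance script uses 8 replicate cohorts and 1000 nulls per test for the
same reason.

## Known limitations

* The shipped 90-region partition is a synthetic stand-in with the right
  module sizes, not an atlas assignment; supply your own table for real data.
* Whole-brain calibration assumes module targets are of the same order as
  the whole-brain target (true of the default regime); wildly heterogeneous
  targets shift the pooled baseline.
* Group comparisons assume homoscedastic residuals (classical
  ANCOVA); no robust/heteroscedastic options are provided.
* Printed-precision inputs propagate: demographic tables recomputed from
  2-decimal summaries can disagree with originally-computed p-values when
  group means differ in the third decimal.
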