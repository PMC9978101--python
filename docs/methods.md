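# Methods

This note documents the models, numerical choices and known limitations of
`dcnet`. It is the design record: every default named here is the package's
own choice, and nothing below states an empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Analysis model

### Preprocessing (per subject)

The stage order is fixed and logged: **discard → FD/exclusion → censor →
nuisance regression → band-pass**. Inputs are an ROI time-series matrix
(T volumes × g parcels) and a 6-column rigid-body realignment trace
(x, y, z in mm; pitch, roll, yaw in radians).

- *Volume discard*: the first `n_discard = 10` volumes are dropped
  (scanner equilibration).
- *Framewise displacement*: FD(t) = Σₚ |paramₚ(t) − paramₚ(t−1)|, with the
  three rotation differences converted to millimetres as arc length on a
  50 mm sphere before summation (the convention of Power-style FD);
  FD(0) = 0. FD is translation-invariant by construction.
- *Exclusion rules*, checked in this order and reported as the first rule
  violated: retained volumes × TR < 3 min after scrubbing FD > 0.2 mm; any
  |translation| > 2 mm; any |rotation| > 2°. `mean_fd`, the head-motion
  covariate used downstream, is the mean FD over all post-discard volumes
  (before censoring), so it is never reduced by the scrubbing itself.
- *Scrubbing* removes flagged volumes from the series used for FC (the
  3-minute rule presupposes frame removal).
- *Nuisance regression*: 24-parameter motion set (6 parameters, their
  one-back values, squares of both), plus the mean across all g parcels as
  the gray-matter-signal proxy — at ROI level no voxel information exists,
  so the parcellation mean is the only available global signal — plus an
  intercept. Ordinary least squares per ROI; a rank-deficient confound
  matrix falls back to the minimum-norm solution (same residuals as dropping
  collinear columns) with a logged warning.
- *Band-pass*: zero-phase (forward–backward) Butterworth, order 2 per pass,
  passband 0.01–0.08 Hz at fs = 1/TR. Filtering is applied after censoring
  on the concatenated retained frames, treated as contiguous — the simplest
  deterministic choice; spectral leakage across censored gaps is a known
  approximation (see Limitations).

### Networks and degree centrality

Functional connectivity is the Pearson correlation of each parcel pair
(g × g, unit diagonal). Binarization is by **sparsity**: at sparsity S the
edge budget is K = round(S·g(g−1)/2) and the K largest correlations become
edges. Edges are ranked by *signed* value (the positive end is retained;
negative correlations can only enter at high S). Boundary ties are broken by
ascending (i, j) order, which makes K exact, the construction deterministic,
and the sweep **nested** (every edge at S is present at S′ > S). Degree
centrality is the adjacency row sum; consequently Σᵢ C_D(Nᵢ) = 2K for every
subject, and group comparisons are of the *distribution* of a fixed edge
budget over nodes, not of overall connectivity strength.

The default sweep is S = 0.05 … 0.40 in steps of 0.01 (36 networks);
tables are reported at S = 0.30. Threshold diagnostics per sweep point:
connected-component count, global efficiency (mean inverse shortest path
over ordered pairs; disconnected pairs contribute 0), local efficiency
(mean over nodes of the neighbour-subgraph global efficiency), average local
clustering C, characteristic path length L (on the largest component when
disconnected, with a log note), and the small-world coefficient
σ = (C/C_rand)/(L/L_rand) against 20 degree-preserving Maslov–Sneppen
rewired nulls (10·|E| swap attempts each, igraph's rewire seeded through a
Python `random.Random`). Low-S disconnection is reported, never "repaired".

### Group inference

Per node, the linear model `DC ~ group + age + sex + education + mean_fd`
(covariates in the model, ANCOVA-style, not residualize-then-test; sex is a
binary indicator, group treatment-coded). The three-group comparison is the
partial F test of the two group columns; Bonferroni across all g nodes
(adjusted p = min(1, p·g)). Post-hoc pairwise comparisons (MDD–HC, SD–HC,
MDD–SD) refit on the two groups' subjects and report the t test of the group
indicator, Bonferroni-corrected over the ANOVA-significant node set — the
post-hoc family follows the ANOVA gate. Because the design matrix is shared
by all nodes, fits are vectorized through one QR factorization per family;
the test suite verifies statistic-level equality with per-node statsmodels
OLS. Degenerate nodes (DC constant across subjects) report F = 0, p = 1.
A covariate that is constant in the sample is dropped with a warning.

Demographics: Pearson chi-squared (no continuity correction) on sex × group;
one-way ANOVA for age and education; two-sample t for BDI-II (SD vs HC).

### Discrimination

ROC analysis uses the criterion "positive if value > c". Orientation is
auto-selected so AUC ≥ 0.5 and recorded (some regions discriminate with
*lower* degree in the affected group). AUC uses the trapezoid / half-tie
(Mann–Whitney) convention; the variance, 95% CI and the test of AUC = 0.5
use DeLong's placement-value estimator with midranks. The Youden cut-off
maximizes sensitivity + specificity − 1 over observed criterion values, ties
broken by higher sensitivity then lower cut-off; sensitivity and specificity
are reported in percent.

The composite index is an **unpenalized** logistic regression on the
flagged regions' DC values, fit by IRLS (Newton scoring) with internal
column standardization for conditioning; coefficients are reported on the
original scale; convergence when max |score| < 1e-8, at most 100 iterations.
Separable data is an *error* (`PerfectSeparationError`), never a silent
divergent fit; saturated fits that meet the score tolerance are caught by a
standardized-coefficient bound (|β| > 15). The composite is evaluated
in-sample by design, mirroring the common practice in small clinical
samples; this overstates out-of-sample AUC (see Limitations).

## Synthetic cohort generator

The generator emulates a three-group cross-sectional rs-fMRI study:
40/34/40 enrolled subjects (HC/SD/MDD), 200 volumes at TR 2.5 s, 246
parcels, with phenotypes drawn to match the emulated study's demographic
table (age, education, sex proportions, BDI-II for HC/SD, HAMD for MDD;
no clinical realism is claimed for the score distributions).

- *Base covariance*: an overlapping-modules factor model — each of k = 10
  latent factors loads on a random ~25% of nodes (loadings N(0.75, 0.15²)),
  plus a weak all-positive global factor (loadings U(0.2, 0.4)) and diagonal
  noise U(0.6, 1.0), rescaled to a correlation matrix. This yields the
  positive-dominant, *modular* structure of real resting-state FC; the wide,
  right-skewed correlation distribution puts a sparsity threshold in a
  low-density region, so degree values are stable across subjects. A dense
  (non-modular) factor model was rejected: its tight correlation
  distribution put the edge threshold in a high-density region and drowned
  planted effects in threshold-crossing noise.
- *Planted effects*: an effect (group, hub, partner count m, delta_r) adds a
  rank-one module factor w·wᵀ with loading √|delta_r| on the hub and its m
  partners, so the hub–partner covariance increment is exactly delta_r
  before re-standardization, and the matrix stays positive definite by
  construction for elevations. Partners are the hub's m most-correlated
  base nodes (its natural community). The loadings are balanced to sum to
  zero over all nodes, making the planted component orthogonal to the
  parcellation-mean signal. This is deliberate: global-signal regression
  forces every node's residual covariance row to sum to −var(node), so any
  planted component aligned with the global mean is removed by preprocessing
  — entry-wise increments projected back to positive-definiteness lose about
  half their amplitude to eigenvalue clipping and the remainder to GSR, and
  are unrecoverable in degree at any sample size. Planting orthogonally to
  the global mean is also the scientifically interesting case: a module that
  reorganizes connectivity without changing the global signal. A consequence
  of module planting is that partners shift with the hub — ground truth for
  recovery tests is the hub node, but the affected neighborhood is wider.
  For elevated-DC recovery experiments the hub is placed on the
  weakest-coupled node (`weakest_hub`): new supra-threshold edges are then
  created rather than redistributed.
- *Time series*: stationary AR(1), x_t = φ·x_{t−1} + √(1−φ²)·ε_t with
  ε ~ N(0, Σ_group); φ defaults to 0.3 (typical rs-fMRI lag-1
  autocorrelation at TR 2.5 s). The marginal covariance equals Σ_group for
  every φ.
- *Motion*: translations follow a random walk with per-step SD 0.01 mm;
  rotations the same on the FD scale (SD 0.01/50 rad, keeping them well
  under the 2° limit except when spiked); Poisson(rate·T) single-volume
  spikes of amplitude 0.3 mm by default (enough to trigger occasional
  scrubbing at the 0.2 mm threshold without excluding typical subjects).
  `plant_motion_failures` injects 3 mm spikes to reproduce exact exclusion
  bookkeeping.
- *Reproducibility*: per-subject generators are keyed (seed, group index,
  subject index), so cohorts are bit-identical across runs and a subject's
  data does not depend on the other groups' sizes.

What the generator does **not** model: hemodynamic response shape,
physiological noise spectra (cardiac/respiratory), spatial autocorrelation
of the parcellation, scanner drift in the BOLD signal itself, or any
coupling between motion and signal (spin-history artifacts). Passing tests
therefore demonstrate that the pipeline recovers covariance-level effects
under realistic temporal structure and motion censoring — not robustness to
artifacts the generator does not produce.

## Problem sizes in the shipped checks

The test suite and acceptance script run at sizes chosen to make the
statistical checks sharp while remaining desk-scale: null calibration uses
3 independent cohorts of g = 200 nodes (600 node-replicates; nodes within a
cohort share the Σ DC = 2K constraint, so replicate cohorts — not more nodes
— supply independence); DeLong coverage uses 500 binormal simulations at
n = 50 + 50; parameter recovery uses g = 60 nodes, n = 30/group, 50
replicates per delta_r ∈ {0.1, 0.2, 0.3}; full-parcellation checks
(g = 246) verify shapes and bookkeeping.

## Numerical choices

- Edge budget uses `round()`; lexicographic tie-break keeps K exact.
- PD repair (needed only for depressed-connectivity effects): eigenvalue
  clipping at 1e-6 then re-standardization to unit diagonal.
- Correlations are symmetrized and clipped to [−1, 1] before thresholding;
  a constant ROI series is an error naming the node.
- The ANCOVA guards the F ratio: numerator mass below 1e-10 of the response
  scale (or a non-finite ratio) reports F = 0, p = 1.
- DeLong: se = 0 (complete separation or pure ties) degenerates to a point
  CI with p = 0 (AUC ≠ 0.5) or p = 1 (AUC = 0.5).
- All output files are written with fixed float formats; rerunning any stage
  on identical inputs is byte-identical (verified in tests).

## Limitations

- Filtering ignores censoring-induced discontinuities; with heavy scrubbing
  the effective passband degrades.
- The gray-matter signal is approximated by the parcellation mean; analyses
  sensitive to the difference between GM-masked voxel means and ROI means
  are out of reach at this data level.
- In-sample composite AUCs are optimistic; a cross-validated variant is a
  config flag (`cross_validate`), off by default to mirror the reference
  analysis, and not wired into the shipped reports.
- Whether negative correlations should compete for edges is debatable;
  signed ranking is the default and the only mode implemented
  (`edge_ranking` records the choice).
- σ estimates at very low sparsity (fragmented graphs) are computed on the
  largest component and can be unstable; the diagnostics table reports
  component counts so such thresholds are visibly unreliable.
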