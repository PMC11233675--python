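# Methods

This note documents the models implemented in volatempo, the numerical
choices behind them, what the synthetic-data generators do and do not
emulate, and the known limitations.  It states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## PARAFAC2 deconvolution

### Model and algorithm

An interval of headspace GC-MS data is a set of K slabs X_k (I_k scans × J
m/z bins) sharing the m/z axis.  The PARAFAC2 model

    X_k ≈ B_k diag(c_k) Aᵀ,   B_kᵀB_k constant over k,

is fitted by the classic direct-fit alternating scheme: write B_k = P_k B
with P_k orthonormal (I_k × F) and B a common F × F matrix.  Each iteration
(1) updates every P_k by an orthogonal Procrustes step (SVD of
X_k A diag(c_k) Bᵀ), and (2) runs one CP-ALS pass on the projected
trilinear array Y_k = P_kᵀ X_k.  Non-negativity on spectra A and
concentrations C uses exact HALS column updates (each column minimised in
closed form, projected to the non-negative orthant), so every block update
decreases the penalized residual: the objective is non-increasing at every
iteration, which the test suite asserts on the recorded loss history.

Numerical choices:

- **Convergence** — relative objective change below `tol` (default 1e-8
  of the total sum of squares) or 2000 iterations.  Standard chemometric
  practice; exactness-sensitive checks (the noiseless core-consistency
  limit) use `tol=1e-13`, where the fit converges to 100% within 1e-9.
- **Restarts** — `n_restarts` (default 10) starts: one SVD-based (spectra
  from the eigenvectors of ΣX_kᵀX_k), the rest random.  All restarts are
  screened for 150 iterations; the best is refined to convergence.
  Screening costs a fraction of running every start to convergence and, in
  the regimes tested, finds the same optimum.
- **Degenerate components** — a HALS column that collapses to zero is
  reseeded at 1e-12 scale so ALS can recover rather than silently carrying
  a dead component.
- **Scale and order conventions** — spectra and the coupling matrix are
  column-normalised with the scale absorbed into C; components are ordered
  by concentration norm.  Factor comparisons in tests always use greedy
  congruence matching, never raw column order, because the model is
  identified only up to permutation (and sign in unconstrained modes).
- **Optional non-negative elution mode** — a flexible-coupling variant
  keeps B_k non-negative with a quadratic penalty μ‖B_k − P_k B‖² whose
  weight increases geometrically.  It is a secondary mode for strongly
  non-Gaussian peak shapes; the default direct fit is used everywhere else.

### Core consistency and component-count selection

The corcondia diagnostic is defined for trilinear models, so it is computed
on the projected array Y: the least-squares Tucker core G of Y against the
fitted factors is compared to the superdiagonal target T,
`100·(1 − Σ(g−t)²/Σt²)`.  A one-component model returns exactly 100 (the
1×1×1 core equals the globally optimal scale, which is 1 at any ALS
stationary point).  Over-factored models collapse, often far below zero.

Selection evaluates F = 1..F_max and keeps candidates with corcondia ≥ 80
whose fit lies within 0.5 percentage points of the best fit observed; these
candidates are fit-wise ties, and the smallest — the most parsimonious
model that explains essentially as much as any other while remaining
trilinear-consistent — is chosen.  A component that buys less fit than the
tolerance is fitting noise, which is exactly the behaviour the corcondia
collapse signals.  Both constants are configuration-exposed: interval-wise
component choice is an operator decision in chromatographic practice, and
these defaults encode the usual judgement.

### Annotation

Estimated spectra are matched to an MSP library by cosine similarity on
m/z-aligned vectors weighted m/z^a·intensity^b with a=1, b=0.5 (classic
identity-search weighting, configuration-exposed).  The consensus apex
retention time (median over samples of each elution profile's maximum) is
converted to a linear temperature-programmed Kovats index,
`100·n + 100·(t − t_n)/(t_{n+1} − t_n)` on the bracketing alkanes, and
compared to the library's retention index within ±30 index units as an
orthogonal identity check.  Components scoring below 0.6 keep a neutral
`component_<f>` name: an honest "unidentified" beats a wrong name.

## Filtering and scaling

Two filters run in fixed order, each emitting a decision report:

1. **Consistency** — a compound is kept iff it is detected (non-missing) in
   all replicates of at least one group × time condition.  One fully
   reproducible condition is evidence the compound is real; scattered
   detections are not.
2. **Coefficient of variation** — per compound, the CV of its condition
   means (sd with n−1 over the group × time cell means, divided by their
   mean); compounds below the threshold (default 0.05) are near-constant
   across the whole experiment and carry no modelling value.  Computing CV
   on condition means rather than raw replicates targets experimental
   variation, not replicate noise.

Both filters are idempotent.  Missing values that survive filtering are
imputed as half the compound's minimum observed positive intensity (the
usual below-detection-limit surrogate) and recorded.  Scaling offers
`unit-sd` (autoscaling), `baseline-sd` (dividing by the baseline-time
standard deviation, preserving effect growth relative to pre-fermentation
variation) and `none` (for data already on a common scale); centers and
scales are stored so the transform is invertible, and zero-variance
variables are rejected rather than silently producing NaN.

## RM-ASCA

### Model

Each variable of the scaled matrix is modelled as

    y = β₀ + Σ_t β_t·1[time=t] + Σ_{t,g} γ_{tg}·1[time=t, group=g] + u_vessel + ε,

with t over non-baseline times and g over non-reference groups; u_vessel is
a random intercept per fermentation vessel (the group × replicate unit —
the repeated-measures subject).  There is no group main effect: the
baseline-interaction removal encodes that groups are indistinguishable
before fermentation starts.  Fixed-effect contributions are assembled into
effect matrices M_time, M_interaction and M_combined = M_time +
M_interaction; each is decomposed by SVD, with explained variance per
component as the squared singular value over the matrix's total sum of
squares.  PCA is reported for the combined matrix by default (one score
trajectory per group per component), with the per-effect decompositions
also available.

### Estimators: GLS versus OLS

GLS at the REML variances equals OLS exactly when the fixed-effect column
space is invariant under vessel averaging (Zyskind's condition).  That
holds for complete balanced time-only designs — the package tests the
equality to 1e-8 there, with strong vessel effects present — but **not**
for the baseline-constrained multi-group model: with the group main effect
removed, the group indicator leaves the column space, and GLS genuinely
reweights the baseline-equality constraint by the vessel variance.  The
package therefore offers two engines and is explicit about which is used:

- `engine="ols"` (default): fixed effects by least squares.  The point
  estimator and every bootstrap refit are then the same projection
  estimator, so the resampling envelopes are calibrated for exactly the
  statistics they cover.
- `engine="mixedlm"`: per-variable REML random-intercept fits via
  statsmodels MixedLM, giving GLS fixed effects plus vessel and residual
  variance components.  Exact interpolation (zero OLS residual)
  short-circuits to OLS with both variances zero, since the REML surface
  is degenerate there; non-convergence falls back to OLS and is flagged.

Sign convention throughout: each component is oriented so its
largest-magnitude loading is positive, making outputs deterministic across
runs and platforms.  The conventional reading — negative loadings mark
VOCs increasing in abundance over time, positive loadings consumption — is
a caption convention that depends on score orientation, stated in the
loading-ranking docstring but never enforced.

### Resampling validation

Vessels are resampled with replacement within group; for every resample
the full pipeline (fixed effects → effect matrix → SCA) is refit, the
components are aligned to the point estimate by greedy congruence matching
with sign flips (threshold 0.5; unmatched components are dropped and
counted), and the group-mean score trajectories and loadings are collected.
Effect matrices are always evaluated on the original design rows so
trajectories are comparable across resamples.  Refits use per-vessel
sufficient statistics (XᵀX and XᵀY blocks), so one refit costs a single
small solve and 1000 resamples run in seconds.

Two small-sample corrections matter at 3 vessels per group and are part of
the method, not tuning:

- **m = n−1 draws per group.** The plain n-of-n bootstrap understates the
  group mean's sampling variance by the factor (n−1)/n — a 33% variance
  deficit at n = 3.  Drawing n−1 vessels per group makes the resampled
  mean's variance unbiased.
- **Interval construction per statistic.** Loadings are norm-constrained
  direction cosines whose resampled values are attenuation-biased (a
  noisier fit rotates the component further toward noise directions), so
  loading envelopes use the basic (reverse-percentile) interval
  [2θ̂ − q_hi, 2θ̂ − q_lo], which undoes that first-order bias.  Group-mean
  score trajectories are approximately unbiased linear functionals, so
  their envelopes use the plain percentile band.  Both are forceable; all
  intervals are clipped to contain the point estimate and collapse to zero
  width when replicate vessels are identical.

With these choices the package's calibration tests find interaction-null
studies fully overlapping at every time point in ≈ 9 of 10 simulated
studies (the residual excess reflects 21 simultaneous band comparisons on
a 216-atom discrete resampling distribution) and 95% loading intervals
covering a known contrast at close to nominal rate.  A leave-one-vessel-out
jackknife is available as an alternative resampling method.

## Profiling

- **Clustering** — compound × (group, time) matrices of replicate-mean
  trajectories, standardized per compound by default so clustering compares
  trajectory shapes; Ward linkage with Euclidean distance via scipy.  Merge
  heights are monotone, so cutting at 2 and refining to 4 clusters is
  consistent.  The test suite validates the linkage against a brute-force
  agglomerator that recomputes Ward's criterion from cluster members at
  every step; on continuous data (ties measure-zero) the sequences agree
  exactly, and exact-tie ordering is delegated to scipy's deterministic
  implementation.
- **Sample PCA** — plain SVD-based PCA with the same sign convention as
  the SCA; used e.g. to verify that sterile-control samples, having no
  temporal evolution, cluster tightly in the score plane.
- **Kinetics** — per compound and group: mean ± sd curves (sd over
  replicates, n−1), the plateau time (earliest design time point with at
  least one later observation from which all later means deviate by at most
  `plateau_tol` × the curve maximum, default 0.05; a curve still moving at
  the last time point has no plateau), the steepest-rise window (largest
  consecutive mean increase, earliest on ties), and final-time intensity
  ranking within the fatty-acid class.  Chain length and odd/even parity
  come from a built-in lookup of common fermentation acids (extensible;
  molecular formulas are parsed; unknown names raise rather than guess).

## Synthetic data: what it emulates, and what it does not

The generators reproduce the *structure* of a longitudinal fermentation
volatilomics study: 4 sample types (inulin, oat bran, fermented and sterile
medium) × 7 time points (0–24 h) × 3 replicate vessels; ~88 compounds in
kinetic classes (acids rising logistically around a 5–7 h midpoint and
plateauing before 16 h, aldehydes/esters decaying, transient intermediates,
near-constant matrix volatiles; sterile controls flat), with oat bran the
strongest producer; interval tensors with exact PARAFAC2 structure, sparse
non-negative spectra on the instrument's unit-mass 35–350 scan range, and
per-sample integer retention shifts.  Elution peaks are Gaussians truncated
at ±4σ so the noiseless cross-product invariance holds exactly rather than
approximately.  Noise is multiplicative log-normal plus additive Gaussian
(GC-MS peak areas show intensity-dependent variance), with a detection
threshold below which values are recorded as missing — never as zero,
since zero is a legitimate intensity.  Replicate-to-replicate variance
magnitudes are configuration parameters, not hard-coded: no published
values exist for them.

The RM-ASCA benchmark generator emits intensities directly in residual-sd
units (effect sizes are specified as multiples of the residual standard
deviation, so the model sees them at face value; autoscaling such data
would divide responding variables by their own signal and shrink the
effects).  Its default conditions are 3 inoculated groups × 7 times × 3
vessels, 40 variables of which 10 rise with 2σ between-group amplitude
steps, vessel intercept sd 0.3.

Passing tests on these generators demonstrates correct recovery of known
structure under realistic noise — they do not demonstrate robustness to
what the generators omit: baseline drift and co-eluting backgrounds beyond
each interval, retention shifts that change peak shape rather than
position, SPME fiber competition/saturation effects, batch effects across
runs, and compound identities beyond a user-supplied library.  Interval
boundaries are user-supplied configuration, as in chromatographic practice;
raw continuous chromatograms are not simulated.

## Problem sizes

Desk-scale defaults keep the full test suite and the acceptance script in
the minutes range on one CPU: 20 simulated intervals of 120 scans × 60 m/z
× 12 samples for factor recovery and model selection; 10 independent study
mimics for loading-recovery statistics; 200 bootstrap resamples per
envelope (1000 remains the library default for analyses); 20 null studies
for calibration; 50 instances for the Ward oracle.

## Known limitations

- The direct-fit ALS can, like all PARAFAC2 fitting, stall in local optima
  for heavily overlapped peaks; restarts mitigate but do not eliminate this.
- Percentile-type bootstrap envelopes at 3 vessels per group rest on a
  216-atom resampling distribution; simultaneous-band error control across
  many time points is approximate (no multiplicity adjustment is applied,
  matching common practice for these envelope plots).
- With `engine="mixedlm"` the bootstrap still refits by OLS for speed;
  on baseline-constrained multi-group designs the two estimators differ
  slightly, so envelope and point estimate are fully coherent under the
  default OLS engine.
- The CV filter assumes intensities on a ratio scale; it is not meaningful
  after signed transformations.
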