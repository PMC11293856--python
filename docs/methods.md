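# Methods

This note documents the statistical model, the defaults and the design
choices behind `admkit`, in the spirit of the methods documentation of
packages like statsmodels or msprime. It states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Compositional preprocessing

Relative-abundance tables carry only ratio information, so all association
analysis happens in centred log-ratio (CLR) coordinates. The preparation is:

1. **Occurrence filter** — keep taxa with raw abundance > 0 in at least
   `min_occurrence` samples (default 10), the standard guard against
   rare-taxon artefacts.
2. **Zero imputation** — multiplicative replacement: every zero becomes
   `0.65 ×` the minimum non-zero value of the table. The minimum is taken
   over the **whole table** (global), the simplest consistent scope; it is
   recorded in the CLR provenance. The operation is idempotent and keeps
   imputed values strictly below any observed one.
3. **CLR** — natural logarithm, centred per sample. The base must be fixed
   because it cancels in `rho` but not in raw CLR values. After the
   transform each row sums to zero to ≤ 1e-9 (a small per-row recentring
   removes accumulated floating-point residue).

Presence/absence for the co-occurrence states is always taken from the
**pre-imputation** table: imputation makes every entry positive and would
otherwise destroy occurrence information.

## Proportionality and its per-sample decomposition

For CLR vectors `m_j`, `m_k` over `n` samples,
`rho = 1 - var(m_j - m_k) / (var(m_j) + var(m_k))` with **population
variances** (divisor `n`). The divisor matters: the exact decomposition
below only holds when numerator and denominator share it.

With `d_i = m_ji - m_ki` and `D = SS(m_j) + SS(m_k)` (sums of squared
deviations), the per-sample contribution is stored in the non-negative form

```
alpha_i = (d_i - mean(d))^2 / D,        rho = 1 - sum_i alpha_i  (exact).
```

Expanding the square gives an equivalent signed polynomial, but the expanded
form is not termwise non-negative and invites sign mistakes; the compact
form guarantees `alpha_i >= 0`, hence `rho <= 1`, and makes the
reconstruction identity hold to machine precision (asserted on 1000 random
CLR pairs at 1e-9).

All-pairs computation uses the rearrangement `rho = 2 cov / (var_j + var_k)`
on a single covariance matrix. Pairs in which both CLR columns are constant
have undefined `rho`; they are excluded with a warning and listed, never
silently dropped.

## Significance thresholds (permutation-bootstrap FDR)

Parametric p-values are unavailable for proportionality, so thresholds are
estimated empirically. Null replicates permute each taxon's sample labels
independently, preserving every marginal distribution while destroying
pairwise covariation — the standard null for co-occurrence analysis. For a
candidate threshold `t` on a grid (−1 to 1 in steps of 0.05, matching the
granularity at which such thresholds are conventionally reported),

```
FDR(t) = mean over replicates of  min(1, #null pairs beyond t / max(1, #observed pairs beyond t)),
```

and the thresholds are the least extreme grid values with FDR ≤ the target
level (default 0.01), one per tail. The procedure is deterministic for a
fixed seed; if no grid value attains the level the error reports the minimum
attainable FDR. Calibration is verified on association-free synthetic
tables (≤ 2% of pairs declared significant on average at the 1% level).

## cADM and rADM

One model per association pair; no multi-task sharing. Learners:
`random_forest` (pinned at 500 trees by default), `gradient_boosting`,
`svm` (RBF kernel), each seeded; any scikit-learn estimator instance is also
accepted. A `memorize` learner (1-nearest-neighbour regression) exists
purely as an exact-interpolation stub for validating the projection scaling.

* **cADM** is a single 3-class classifier (not three one-vs-rest models) of
  the per-sample state: co-presence (both raw abundances > 0), co-absence
  (both 0), exclusion (exactly one > 0). Performance is the mean **balanced
  accuracy** over stratified 5-fold cross-validation — the natural choice
  for imbalanced 3-class labels. Pairs with a single state, or whose rarest
  state has one member, cannot be fit or cross-validated and are skipped in
  the pipeline with a log entry.
* **rADM** regresses `alpha_i` on the predictors; performance is mean
  **R²** over shuffled 5-fold cross-validation. A constant target warns and
  fits a constant predictor with undefined (NaN) R².

Cross-validation never evaluates on training folds; on noise targets
performance sits at the chance level (checked by simulation). Fold
assignment and estimators share one seed, so identical calls reproduce
identical performance values.

**Permutation feature importance.** `importance(f) =` mean over `n_repeats`
seeded shuffles of feature `f`'s column of (baseline score − shuffled
score). Implemented directly from this definition; the test suite
cross-checks it against an independent library implementation. Importances
may be slightly negative for useless features; permuting a constant column
yields exactly zero.

**Model retention.** Downstream stages keep models for significantly
positive pairs whose cADM balanced accuracy and rADM R² clear configurable
floors (defaults 0.5 and 0.0). The floors are configuration knobs, not
scientific constants.

## Projection

Grids are flat lists of cells (1°-style climatologies or coarser) carrying
the same predictors as the training samples.

* **Sample ↔ grid mapping** uses the exactly matching valid cell when one
  exists, otherwise the mean of valid cells within a ±2° latitude/longitude
  box. A box rather than a great-circle disc: at 1° resolution the
  difference is negligible and the box is unambiguous. Samples resolving to
  no cell are returned in a rejection report. Longitudes are normalised to
  [−180, 180); no wrap-around averaging across the antimeridian in this
  version.
* **Range masking**: a cell is projectable only if **every** predictor lies
  within the [2.5, 97.5] percentile envelope of the observed samples.
  Masked cells receive *no* prediction — the framework refuses to
  extrapolate. Widening the envelope can only grow the valid set
  (property-tested).
* **rho\* scaling**: training defines `rho` over `n` samples, but a grid
  has `G` valid cells, so the projected sum is rescaled:
  `rho* = 1 - (n/G) · sum(alpha*)`. This is the unique linear scaling under
  which a grid that replicates the training samples reproduces the training
  `rho` exactly — validated by projecting a memorizing rADM onto its own
  training features (agreement to 1e-9). Regional `rho*` applies the same
  formula over a region's cells; consequently the cell-count-weighted mean
  of regional `1 - rho*` over a partition equals the global value. `rho*`
  can exceed [−1, 1] for a poorly matched grid; the raw value is preserved
  and clipping happens only at reporting time.
* **Regions** are named latitude/longitude rectangles, required to be
  disjoint; full ocean-province polygons are out of scope.

## Community structure

The stacked matrix (associations × valid cells, 1 = predicted co-presence)
is clustered with k-means — Euclidean distance on the raw 0/1 matrix, 10
restarts per k, fixed seed — for k from 2 to 15; the retained k maximises
the mean silhouette (computed on at most 5000 seeded-sampled rows for
tractability). k values exceeding the number of distinct rows are skipped;
if no k admits a silhouette (e.g. all rows identical) the call fails
explicitly. Per-cluster graphs take taxa as nodes and associations as edges
weighted by projected `rho*`. Edge betweenness centrality is computed on
the **unweighted** shortest-path structure: distance semantics for `rho*`
weights are undefined (a stronger association should arguably be a
*shorter* edge, an inversion no convention fixes). Edge density is reported
as the edges-per-node ratio `E/N`, the edge-level measure used in this
field's network analyses; the conventional `2E/(N(N-1))` is exposed
separately as `conventional_density` to avoid confusion. Cross-cluster
metric comparisons are min-max normalised with the relative spread
`(max - min)/max × 100` reported alongside; all-equal values map to 0 with
spread 0 (documented convention).

## Temporal response

Projections are tracked over calendar years (2015 plus 2020–2100 in 10-year
steps, 10 time points, when emulating a century-scale scenario). Only
associations keeping ≥ 30% co-presence at **every** time point are
classified, so trends concern associations that persist in the projected
area. Per-year OLS slopes of co-presence proportion and `rho*` (with
Pearson r and R² as linearity diagnostics) feed the grouping rule:

* the neutral band of each metric is ± `band_fraction` (default 10%) of the
  largest absolute slope of that metric — making the partition invariant to
  rescaling either metric; an alternative `band_mode="quantile"` (central
  10% of the slope distribution) is provided because the "10% around zero"
  convention admits both readings;
* neutral ⇔ **both** metrics inside their bands; otherwise the group is the
  raw sign pattern `(±c)(±r)`. A metric inside its band while the other is
  outside contributes its raw sign (the five groups leave no room for
  half-neutral labels); an exactly-zero slope in that mixed case is
  labelled `+` by convention — a measure-zero edge case.

Constant series get slope 0 with missing (NaN) diagnostics. Recovery of
planted trajectory patterns is verified at 100% without noise and ≥ 90%
under moderate noise across 50 seeded replicates.

## Synthetic worlds

The generator emulates the structure of the real inputs, not their content:

* **Environment** — temperature falls linearly with |latitude|
  (28 °C at the equator, −0.3 °C per degree, sd 1 noise); nitrate and
  silicate are drawn conditionally on standardised temperature to hit
  target Pearson correlations of −0.9 and −0.7 (surface-ocean nutrient
  structure is strongly anti-correlated with temperature); salinity is
  35 PSU ± 0.1 noise. Samples sit at uniform random latitudes (±65°).
* **Taxa** — Gaussian thermal niches (optimum uniform over the sampled
  temperature range, breadth 6–10 °C); log-abundance = baseline + 5 × niche
  response + N(0, 0.15); the taxon is structurally absent where the niche
  response falls below 0.3 (truncation, not random dropout, so
  presence/absence carries environmental signal). Rows are closed to
  relative abundances.
* **Planted pairs** — positive pairs share a latent log-abundance factor
  (weight 2) and a habitat window, with thermal optima offset by 4 °C so
  the pair's log-ratio divergence — hence `alpha` — varies smoothly with
  temperature: the association strength itself has an environmental
  gradient to learn. Negative pairs receive the latent factor with opposite
  signs and mirrored thermal optima (mutual exclusion). The default world
  is 80 samples × 50 taxa with 20 planted positive pairs.
* **Climate trajectories** — per-decade linear warming (default 0.3 °C),
  geometric nitrate decline (default 5%/decade; silicate at half that
  rate), salinity unchanged, optional cell noise.

All generators are pure functions of (spec, seed).

What the worlds do **not** emulate: real taxon composition, spatial
autocorrelation of residuals, seasonality, depth structure, bathymetry and
ocean-province geometry, or detection noise of sequencing pipelines.
Passing tests therefore demonstrate that the machinery recovers structure
it is designed to detect under a faithful-but-simple generative model — not
that real plankton data satisfy that model.

## Problem sizes and numerical choices

Test and acceptance workloads use deliberately small configurations chosen
by the package — e.g. 30–100 bootstrap replicates, 20–200 trees per forest,
coarse (5°×10°) grids, 4–10 time points — which the statistical assertions
are calibrated for. Tolerances: CLR closure and decomposition identity
1e-9; oracle equivalence 1e-12; round-trip serialization 15 significant
digits. k-means ties and learner-comparison ties break deterministically
(silhouette ties prefer smaller k; equal performance sorts by learner
name).

## Known limitations

* No spatial cross-validation: CV folds ignore spatial autocorrelation, so
  reported skill can be optimistic on gridded data.
* No hyperparameter search; learner defaults are pinned for
  reproducibility, not tuned.
* Association ≠ interaction: `rho` is a statistical proxy; it cannot
  separate direct interactions from shared environmental preference.
* Regional analysis is rectangle-based; no polygon provinces.
* The antimeridian is not wrapped when averaging grid neighbourhoods.
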