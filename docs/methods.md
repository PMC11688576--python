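# Methods

`ordimpute` benchmarks single-imputation methods on ordinal questionnaire
data. Everything below is the package's own account of what it computes,
the assumptions behind each component, and the choices made where the
design was genuinely open.

## Synthetic scale data

Short stress questionnaires (ten items scored 1–5) are unidimensional and
positively inter-correlated. The generator emulates this with a
one-factor normal-ogive model: respondent *i* carries a latent trait
*z_i* ~ N(0, 1); item *j* has loading λ_j ∈ (−1, 1); the continuous
response is

    y_ij = λ_j z_i + sqrt(1 − λ_j²) ε_ij,   ε_ij ~ N(0, 1),

cut at fixed thresholds t_1 < … < t_{K−1} into K ordered categories
(category = 1 + number of thresholds below y). Because y_ij is standard
normal marginally, the thresholds are normal quantiles and the latent
inter-item correlation is λ_j λ_k.

Defaults: 10 items, 5 categories, all loadings 0.6 (latent r = 0.36 —
clearly correlated, far from degenerate), thresholds Φ⁻¹(0.2, 0.4, 0.6,
0.8) giving equal 20% marginal mass per category. Reverse-keyed items
flip the loading sign. All defaults are constructor arguments.

What this emulates and what it does not: the generator reproduces the
unidimensional positive-manifold correlation structure and the 1–5
ordinal support of a perceived-stress scale. It does not reproduce
skewed category distributions, multidimensional content, respondent
styles (straight-lining, acquiescence) or demographic covariates. Results
on this data therefore speak to ranking imputers under a clean
unidimensional structure, not to every pathology of field data. A CSV
loader accepts real scale data as a drop-in replacement.

## Missingness mechanisms

Missing marker is IEEE NaN throughout; CSV serialization uses empty cells.

**MCAR** hides every cell independently with a fixed Bernoulli rate.

**MAR** keeps a random subset of "pillar" columns fully observed
(`ceil(observed_fraction · p)` of them, default fraction 0.3) and hides
each remaining cell with a per-row probability `sigmoid(w·x_pillars + b)`,
with w ~ N(0, I) on the standardized pillar values drawn fresh for every
mask replicate. The intercept b is found by bisection over [−50, 50]
(mean-sigmoid is continuous and strictly increasing in b, so the bracket
always works; tolerance 1e−6, cap 200 iterations).

The calibration target is the **overall** matrix rate: the per-maskable-
cell target is inflated by p/(p − n_pillars) so that MCAR and MAR
conditions are comparable at equal nominal rates — the benchmark metric
averages over the whole matrix, so equal overall rates are what makes
cells comparable across mechanisms.

## Imputers

All imputers share one contract (sklearn transformer: `fit` then
`transform`): observed cells pass through bit-identical, output is
complete, fixed seed ⇒ identical output.

* **mean / median** — column statistic of observed values.
* **em** — EM for a multivariate normal (μ, Σ): per-row conditional
  moments of the missing block accumulate expected sufficient statistics;
  Σ uses the ML 1/n normalization; stopping when the max relative change
  over all entries of μ and Σ — |θ_new − θ_old| / (|θ_old| + 1e−8) —
  falls below 1e−4, cap 1000 iterations. Observed-data log-likelihood is
  tracked per iteration and tested non-decreasing. Near-singular observed
  blocks (few ordinal categories can collapse variance) are solved by
  Cholesky with a 1e−8·trace/p ridge fallback. Imputation is the
  conditional mean plus, by default, a residual drawn from the
  conditional covariance — the conditional rather than the unconditional
  covariance, because that is the distribution the missing block actually
  follows given the observed block. `stochastic=False` gives the
  deterministic regression imputation used by the closed-form tests.
* **knn** — k = 3, uniform weights, missing-aware Euclidean distance
  scaled by sqrt(p / n_shared) (the convention of
  `sklearn nan_euclidean_distances`, which provides the distance matrix);
  donors for cell (i, j) are rows with column j observed; ties break
  toward the lower row index; no donors ⇒ column mean. No
  standardization: all items share the 1–5 scale.
* **missforest** — mean-initialize; visit columns by ascending missing
  count (ties by index); per column fit a 100-tree regression forest
  (sklearn `RandomForestRegressor`, mtry = ⌊p/3⌋, bootstrap) on rows with
  the column observed and predict its missing cells; after each sweep
  compute Δ = Σ(X_new − X_old)² / Σ X_new² over originally-missing cells
  and stop when Δ rises, returning the pre-rise imputation; cap 10
  sweeps. Out-of-bag R² is recorded as a diagnostic only.
* **autoencoder** — p→7→5→3→5→7→p MLP, ReLU on hidden layers, linear
  bottleneck and output; columns standardized on observed moments,
  missing cells zero-filled (= column mean in standardized space);
  full-batch Adam, lr 1e−3, 100 epochs. The loss is MSE over *observed*
  cells by default — scoring the artificial zeros at missing cells is a
  known artifact — with `loss="full"` available to reproduce the
  zero-target variant. Full-batch because n ≤ 1000, p = 10 makes
  minibatching pointless.
* **remasker** — masked-autoencoding transformer. Cell (i, j) becomes a
  token x_ij·v_j + pos_j with learned per-feature vectors; per epoch each
  row re-masks a uniform random half (mask_ratio 0.5) of its observed
  cells; a pre-norm transformer encoder attends only over visible tokens
  (additive −1e9 key bias), the decoder sees encoder outputs at visible
  positions and a shared learned mask token plus positional embedding at
  hidden ones, and a linear head reconstructs every cell; MSE loss on the
  re-masked observed cells only; features min-max scaled to [0, 1] on
  observed values and un-scaled before rounding. Defaults: embed 32,
  encoder/decoder depth 4/2, 4 heads, 300 epochs, Adam lr 1e−3.

The two neural imputers run on a small numpy reverse-mode autodiff engine
(`ordimpute.nn`) written for this package — broadcasting arithmetic,
fused linear, batched matmul, softmax with additive bias, layer norm —
with every gradient verified against central finite differences in the
test suite. The transformer trains in float32.

## Evaluation

Imputed values are rounded half-away-from-zero to the nearest integer
(banker's rounding would bias toward even categories) and clipped into
[1, 5] — clipping is required because EM-with-residuals and the networks
are unbounded. The score is

    RMSE = sqrt( (1/(n·p)) Σ_ij (x_ij − x̂_ij)² )

over all n·p cells of the ground-truth vs. imputed matrix; a
`rmse_masked` variant restricts the average to hidden cells (the
full-matrix value dilutes the signal by the missing rate — for
pass-through imputers rmse_full = rmse_masked·sqrt(m/np) exactly).
Aggregation across replicates reports mean, sample (n−1) SD, min, max;
a single replicate reports SD = 0 by convention.

## Experiment design and seeding

The full grid crosses sample sizes (200, 500, 1000) × missing rates
(5, 10, 15%) × mechanisms (MCAR, MAR) × 7 methods × 10 mask replicates =
1260 records. Every seed is a SHA-256 hash of (base_seed, role,
condition tuple): mask seeds exclude the method name, so all methods see
the *same* mask within a replicate (a paired comparison — the fair way to
rank methods; toggleable via `paired_masks`); imputer seeds include it.
Data matrices are drawn independently per sample size (not nested — the
sizes are separate draws of respondents) and reused across
mechanism/rate conditions so only the masks vary. One imputer failure
skips its cell with a logged error instead of aborting the grid.

## Problem sizes in the shipped checks

The test suite and `scripts/acceptance.py` exercise the pipeline at
sizes chosen to keep a full run on one CPU in minutes: the headline
ranking check uses n = 500, rates {5%, 15%}, both mechanisms, 10 paired
masks, with the transformer in a reduced configuration (embed 16, depth
2/1, 2 heads, feed-forward multiplier 2, 150 epochs) that trains the
same architecture at desk scale; the acceptance script benchmarks all
seven methods at n = 500, 10% missing, 5 replicates per mechanism. The
full-size defaults remain available through the config/CLI for complete
runs.

## Known limitations

* The MAR weight scale ("random weights" on standardized pillars ~
  N(0, 1)) is a convention; masks should be reported with their seed
  protocol.
* The EM residual draw uses the conditional covariance; packages that add
  residuals from the unconditional covariance will disagree slightly in
  distribution (not in the deterministic conditional mean).
* All methods impute on the continuous scale and are only discretized at
  scoring time; no categorical-mode branches (mode imputation,
  classification forests) are provided.
* MNAR mechanisms, multiple imputation (MICE-style pooling), and
  hyperparameter search are out of scope.
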