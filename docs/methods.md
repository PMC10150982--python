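# Methods

This note documents the models, numerical choices and synthetic study
conditions behind `songdev`, in the order the pipeline runs them.

## The scientific question

Juvenile male zebra finches copy a tutor's song over weeks of practice
(roughly 60–95 days post hatch, dph). Two circadian phenomena interact with
this long-term learning: song is more variable in the morning than in the
evening, and the apparent maturity of song changes overnight in a way that
depends on which quantile of the maturity distribution one examines (the
least mature renditions appear to "regress" overnight; the most mature ones
progress). `songdev` implements an analysis chain that asks whether the
first phenomenon is sufficient to produce the second: if rendition-to-
rendition variability (distribution entropy) is high each morning and low
each evening, a morning's wider distribution mechanically contains both
more-regressive and more-progressive variants than the previous evening's
narrower one — no overnight movement of the distribution mean is needed.

## Data model

A **rendition** is one production of a syllable type, represented as a row
`(bird_id, syllable_id, age_dph, time_of_day_h, day_index, z1..zk)` where
`z` is a k-dimensional latent acoustic vector (6 ≤ k ≤ 8 in practice).
Latents can come from any external encoder (e.g. the posterior mean of a
spectrogram VAE) or from the built-in feature path (below). All downstream
stages operate on this flat table.

## Feature path (`songdev.features`)

- **Segmentation**: the RMS amplitude envelope (5 ms window) is thresholded;
  supra-threshold runs separated by less than `min_gap` seconds are merged
  and runs shorter than `min_duration` are dropped. Intervals are 0-based
  half-open sample ranges. The threshold is data-dependent and must be tuned
  per recording setup.
- **Spectrograms**: log-magnitude short-time Fourier transform (512-sample
  Hann window, 128-sample hop) mapped through a 128-filter triangular mel
  bank (HTK mel scale, 0 Hz to Nyquist), clipped to a `[floor, ceiling]`
  dynamic range, affinely rescaled to [0, 1], and symmetrically zero-padded
  in time to a 128×128 image. At 44.1 kHz the 128-frame limit corresponds to
  ~0.38 s, comfortably above zebra finch syllable durations. Window/hop and
  floor/ceiling are package defaults, all overridable; real deployments tune
  them per bird.
- **PCA features**: within-syllable PCA over flattened spectrograms (or over
  external latents), truncated at the *effective dimensionality* k = the
  smallest component count explaining > 99% of variance. If the threshold is
  only reachable through numerically zero eigenvalues, k falls back to the
  numerical rank with a recorded warning.

## Predicted age (`songdev.maturity`)

The maturity score is the output of a small feedforward regressor from
latent coordinates to production age (days). Hidden layers use tanh; presets
are sized so that a 32-d input gives the canonical parameter counts of this
model family: `pyramid` 32–16–8–4–1 (705 parameters), `shallow` 32–16–4–1
(601), `linear` (no hidden layer; identical function class to ordinary least
squares, and verified against the closed form in the tests).

Training minimizes mean squared error plus an L2 penalty on connection
weights. Data handling: the caller first makes an 80/20 train/evaluation
split; `train_age_net` re-partitions its input 70/15/15 into fitting, test
and validation subsets. Optimization is full-batch L-BFGS; after each
iteration the test-subset MSE is evaluated and training stops when it fails
to improve for three consecutive iterations, restoring the best iterate
(`patience=None` disables this and runs to convergence). The L2 weight is
chosen on the validation subset from the grid {1e-6, 1e-4, 1e-2} unless
fixed by the caller; this replaces adaptive Bayesian-regularization
weighting with an explicit, reproducible selection of the same two-term
objective. Inputs are standardized internally (constants frozen into the
model); predictions are a pure function of the latent input.

**Permutation controls.** `shuffle_mse` re-scores the held-out split (ages
restricted to 60–95 dph) after permuting production ages relative to
latents: `total` permutes freely, `within_day` permutes only among
renditions of the same `day_index`, so only sub-circadian structure is
destroyed. The report carries the full permutation MSE distribution and the
exceedance fraction (share of permutations strictly worse than unshuffled).

## Time-varying Gaussian model (`songdev.devmodel`)

Each syllable's renditions are modeled as draws from N(mu(t), Sigma(t))
where t is the production time encoded as `[z_age, sin(2*pi*tod/24),
cos(2*pi*tod/24)]`; the circadian pair takes identical values at the same
clock time on different days, and z-scoring constants for age are computed
on the training side only and frozen. A ReLU MLP maps this 3-vector to
`(mu, l, d)`: `l` fills a lower-triangular L and

    Sigma = L L^T + diag(exp(d) + eps),    eps = 1e-4,

which is symmetric positive definite by construction for any output. `eps`
conditions the Cholesky without distorting entropies at the data scale and
is configurable. Architecture presets (hidden layers × width): `wide`
3×256, `shallow` 2×256, `narrow64` 3×64. These sizes reproduce the
reported parameter-count families exactly (wide: 141,089 at k=6 to 143,402
at k=7; shallow: 75,297–80,180; narrow64: 10,721–11,956 for k=6–8) and are
asserted in the tests.

Training minimizes the *mean* per-rendition negative log likelihood (the
sum and the mean share an optimum; the mean keeps the Adam learning rate
meaningful across batch sizes) with Adam (lr 1e-3), mini-batches of 512
reshuffled each epoch under the run seed, on an internal 80/20 re-split of
the training side; early stopping restores the best internal-test
checkpoint with patience 10 (default). Gradients are computed analytically
(the dSigma-chain through L and d) and were verified against finite
differences at 1e-9 agreement. The output head is initialized at data
moments — mu bias at the latent mean, d bias at the log marginal variances,
small random weights — so the first iterations start from a sensible
diagonal Gaussian; this is standard density-network practice and makes
short trainings stable.

`eval_loglik` mirrors the maturity controls: held-out mean log likelihood
against `total` and `within_day` permutations of production times relative
to latents (wrong-day associations prohibited in the within-day null).
Snapshots are precomputed once per rendition, so each permutation costs one
batched triangular solve.

## Entropy analysis and clamping (`songdev.entropy`)

Differential entropy of a fitted snapshot: `H = 1/2 ln|Sigma| + k/2 (1 +
ln 2*pi)` (nats; natural log throughout). Model entropy is sampled at
5-minute query times inside the lights-on window; a query time is retained
only if the centered 30-minute window (closed on both ends) contains at
least `min_count` training renditions of that syllable that day. The
package default is `min_count=30`. In reduced-scale synthetic corpora this
filter must be scaled with the singing rate: at 200 renditions/day spread
over 14 h the expected count per half-hour window is ~7, so the tests and
the acceptance script use `min_count=5` there (and keep 30 whenever the
corpus is dense enough to support it). The threshold's exact behavior (29
renditions → dropped) is unit-tested at the default value.

**Circadian entropy regression**: `entropy ~ 1 + timeOfDay` with correlated
random intercept+slope at the bird level and random intercept+slope at the
syllable level; a secondary variant adds age and the age-by-time-of-day
interaction with random effects for all coefficients. See "Mixed models"
below for the estimation machinery.

**Clamping**: `fix_entropy(Sigma, target_det)` eigendecomposes Sigma and
divides every eigenvalue by `(det(Sigma)/target_det)**(1/k)`. The eigenbasis
and all eigenvalue ratios — the *allocation* of variation — are preserved
exactly; the determinant lands on the target to ~1e-14 relative and the map
is idempotent. The per-day target is the minimum determinant over that
day's retained query grid (the raw observation times are also accepted; the
grid is the default because it matches the entropy analysis support and
avoids extrapolation).

**Simulation**: for every held-out observation time, one draw from the
model's Gaussian at that time (`baseline`) or from the day-clamped Gaussian
(`fixed_entropy`), via the Cholesky factor applied to a standard normal
vector from a per-observation counter-derived substream. Timestamps are
carried over; days without a computable target are skipped with a logged
warning. The clamp never moves the mean, so the two conditions differ only
in within-day entropy.

## Overnight shifts (`songdev.shifts`)

Renditions with predicted ages are binned by production time into 0.1-day
bins anchored at integer dph (midnight; the anchor is configurable). Bins
with fewer than 30 renditions are discarded. Within each retained bin,
empirical quantiles are taken at levels {1, 5, 25, 50, 75, 95, 99} (or the
3- and 11-level alternates) using linear interpolation between order
statistics (numpy's default, type 7); the estimator matters for the 1st and
99th percentile in 30-rendition bins and is therefore configurable. For
each consecutive day pair the shift at level i is the level-i quantile of
the first bin of day j+1 minus that of the last bin of day j, discarded
when the two bin centers are more than 0.6 days apart.

The shift regression is `shift ~ 1 + percentile` with percentile scaled to
[0, 1]; the simulation contrast adds a fixed-entropy indicator and its
interaction with percentile (`shift ~ 1 + percentile * condition`), with
random effects at the bird and syllable levels. Per-level marginal effects
and the clamped-condition net slope are obtained as Wald linear
combinations of the fixed effects.

## Mixed models (`songdev.lmm`)

All hierarchical fits go through statsmodels MixedLM with the bird as the
grouping factor: correlated random intercept/slope pairs at the bird level
(`re_formula`) and variance components for the syllable level (syllables
are nested within birds). statsmodels variance components are mutually
independent, so syllable-level intercepts and slopes are uncorrelated — a
mild restriction relative to a fully correlated syllable-level covariance;
the test suite cross-checks fixed effects against lme4's fully correlated
fit (via Rscript) and finds agreement within one standard error. REML is
the default; maximum likelihood is available for fixed-effect structure
comparisons.

Inference uses a t reference with between-groups degrees of freedom
(number of birds − 1) rather than the Wald normal: with five birds the
normal reference undercovers the intercept (0.82 observed in a 50-replicate
calibration), and the t correction restores ≥ 0.95 coverage. This is
standard small-sample mixed-model practice and is applied uniformly to
p-values, confidence intervals and linear-combination tests.

Degenerate inputs are handled by tiered fallback — full structure, then
bird-level random effects only, then OLS — with every step recorded in the
result's notes and flags. For an exactly linear noise-free response any
generalized-least-squares weighting returns the generating coefficients, so
the OLS fallback is the correct limit, not an approximation. A fit with a
variance component at the boundary is returned flagged as singular, never
silently.

## Synthetic study conditions (`songdev.synthetic`)

The generator emulates the statistical structure the analyses assume:

- **Corpus shape** (defaults): 5 birds × 13 syllables, k = 6, 60–95 dph,
  lights-on 07:00–21:00 (14 h), ~200 renditions per syllable per day drawn
  uniformly within the window (real finch singing is denser in the morning;
  the uniform rate is a deliberate simplification — see Limitations).
- **Mean path**: each syllable's cluster center drifts along a fixed random
  direction by 5 latent units over the age range. By default progress
  accrues in *song time* — only while the bird is singing — so the mean is
  exactly unchanged overnight. This is the condition under which any
  quantile-dependent overnight shift must come from variability, not mean
  regression. A `continuous` mode (linear in age) is available.
- **Entropy schedule**: linear within the day (default 1.0 nat decline per
  lights-on window, i.e. ~0.071 nats/h over 14 h, matching the reported
  scale of circadian entropy decline in latent song spaces) plus a linear
  developmental trend (−0.033 nats/dph). Entropy is realized by isotropic
  scaling of a per-syllable eigenvalue spectrum (geometric decay, geometric
  mean normalized to 1) in a slowly rotating eigenbasis (1°/day), so
  allocation and entropy are independently controllable and the true
  entropy has a closed form shared by all syllables. The generator rejects
  parameter sets whose implied eigenvalues underflow, naming the offending
  time.
- **Seeding**: one master seed; every (bird, syllable) block draws from a
  counter-derived substream, so any subset regenerates identically.
- **Toy audio**: harmonic-stack syllables (fundamental and duration varying
  smoothly with age) embedded in silence at 44.1 kHz, for exercising the
  feature path end to end.

Within a generated day the eigenbasis rotation is evaluated at the day's
midpoint (the sub-day rotation at 1°/day is negligible); the closed-form
accessors use the exact age.

### Problem sizes used in tests and acceptance

Reduced-scale conditions were chosen once, as realistic configurations of
the same schedules, and are not tuned per run:

- *Parameter recovery / shuffle orderings*: 2 syllables × ~6,000 renditions
  (200/day over 30 days), `narrow64` density nets, 200 permutations.
- *Headline mechanism*: 4 birds × 2 syllables, 2,000 renditions/day over
  60–75 dph — dense juvenile singing that keeps every 0.1-day bin of the
  20% evaluation split above the 30-rendition bin filter — with a 12-h
  lights-on window (07:12–19:12) aligned to bin edges so all bins lie fully
  inside the singing window; three independent seeds.
- *Mixed-model calibration*: 5 birds × 13 syllables (3/3/3/2/2), 50
  replicates with random effects at both levels.

## What passing tests do and do not show

The synthetic corpora contain exactly the structure the models assume:
Gaussian rendition distributions, linear entropy schedules, smooth mean
drift, uniform singing rate. Passing tests therefore demonstrate that the
implementation recovers known structure and that the entropy-clamping
counterfactual behaves as specified — they do not certify performance on
real recordings, where distributions are non-Gaussian, singing is bursty
and morning-skewed, syllable labels can be noisy, and encoder latents carry
their own biases. The feature path's thresholds (segmentation amplitude,
spectrogram floor/ceiling) must be hand-tuned per dataset, as in any
amplitude-based bioacoustics pipeline.

## Known limitations

- Sequencing/syntax across syllables and protosyllable differentiation
  before 60 dph are out of scope; datasets arrive labeled.
- The density model covers the top-k principal subspace, not the full
  latent space; k > 8 presets are untested.
- Syllable-level random effects are uncorrelated (variance components);
  lme4 is the cross-check, not the engine.
- The fitted mean near the lights-on/lights-off edges is the least
  constrained part of the density model; at desk scale this is the dominant
  noise source in overnight comparisons, which is why the mechanism
  analyses benefit from dense corpora.
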