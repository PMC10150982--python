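# songdev

Latent-space analysis of juvenile birdsong development: data-driven
maturity scoring, time-varying Gaussian models of syllable distributions
with circadian covariates, differential-entropy analysis with a
determinant-clamping counterfactual, and quantile-wise overnight maturity
shift statistics.

## The problem

Juvenile male zebra finches learn song by practicing thousands of syllable
renditions a day over weeks (~60–95 days post hatch). Their song is more
variable each morning than each evening, and its apparent maturity changes
overnight in a quantile-dependent way: the least mature renditions seem to
regress overnight while the most mature ones progress. `songdev` implements
the modeling chain needed to test whether the circadian *variability*
pattern alone produces the overnight *maturity* pattern — without any
overnight regression of the underlying distribution mean.

The chain, for each syllable type (a cluster of renditions in a
k-dimensional latent acoustic space):

1. **Predicted age** — a small network maps a rendition's latent vector to
   a maturity score in days, validated against total and within-day
   permutation nulls.
2. **Time-varying Gaussian model** — a density network maps production time
   `[z-scored age, sin(tod), cos(tod)]` to a full Gaussian
   `Sigma = L·Lᵀ + diag(e^d + ε)`, trained by maximum likelihood.
3. **Entropy** — `H = ½ ln|Σ| + (k/2)(1 + ln 2π)` nats, sampled on a
   support-filtered 5-minute query grid and regressed on time of day in a
   hierarchical model (random intercepts/slopes by bird and syllable).
4. **Entropy clamping** — `Σ_fixed = Q (Λ / ratio^{1/k}) Qᵀ` pins each
   day's covariance determinant to the day's minimum, preserving the mean
   and the allocation of variation exactly.
5. **Overnight shifts** — simulated (baseline vs fixed-entropy) renditions
   are scored, binned into 0.1-day bins, and per-percentile overnight
   shifts are regressed on percentile level crossed with condition.

A synthetic-data module generates developmental corpora with known ground
truth (drifting cluster means that advance only during singing hours,
linear within-day and developmental entropy schedules, day/night singing
windows), so every stage is testable without recordings.

## Worked example

`examples/` holds one short script per capability. The headline mechanism
(`examples/06_overnight_shifts.py`, ~1 minute) generates a corpus with
morning-high/evening-low entropy and *no* overnight mean change, fits both
models per syllable, simulates development with free and clamped entropy,
and fits the shift regression:

```
616 overnight shift records ({'baseline': 308, 'fixed_entropy': 308})
  Intercept            -0.203 +/- 0.233  p = 5.44e-01
  percentile01         +0.672 +/- 0.241  p = 2.19e-01
  cond                 +0.396 +/- 0.238  p = 3.45e-01
  percentile01:cond    -0.718 +/- 0.104  p = 9.15e-02

baseline percentile slope: +0.672 days (p = 0.219)
fixed-entropy net slope:   -0.046 days (p = 0.881)
```

Reading: in the baseline simulation, overnight shifts increase by ~0.67
predicted-age days as the percentile runs from 0 to 1 — the low quantiles
regress, the high ones progress — and the interaction with the
fixed-entropy condition cancels that slope almost exactly (net slope
−0.05). Clamping within-day entropy, while leaving the mean and the
allocation of variation untouched, removes the quantile dependence: the
morning expansion of variability, not overnight mean movement, creates the
pattern. (This 2-bird demo uses very conservative small-sample inference;
the 4-bird configuration in the test suite yields the same pattern with a
clearly significant baseline slope.)

Other examples print the closed-form entropy/clamping identities (05), the
shuffle-control orderings for both models (03, 04), the audio → spectrogram
→ PCA feature path (02), and the generator's structure (01).

A one-command pipeline over a YAML config is also available:

```bash
songdev run --config run.yaml --seed 7    # stages: synthetic ... shifts
songdev validate dataset.csv              # schema/consistency report
```

## Layout

```
src/songdev/
  synthetic.py   ground-truth corpora, closed-form entropy, toy audio
  features.py    segmentation, mel spectrograms, effective-dimensionality PCA
  maturity.py    predicted-age networks + shuffle controls
  devmodel.py    time-varying Gaussian density networks
  entropy.py     entropy trajectories, circadian LMM, clamping, simulation
  shifts.py      time-binned quantiles, overnight shifts, shift LMMs
  lmm.py         hierarchical-model machinery (bird/syllable random effects)
  pipeline.py    config-driven orchestration + dataset validation
  cli.py         `songdev run|validate`
docs/methods.md  models, assumptions, numerical choices, limitations
```
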