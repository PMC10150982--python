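"""End-to-end mechanism demo: circadian entropy fluctuations generate
quantile-dependent overnight maturity shifts without overnight regression.

Generates a corpus whose cluster means advance only while the bird sings
(no overnight mean change) but whose entropy is high each morning and low
each evening.  Development is then simulated from trained Gaussian models
at held-out production times, twice: as fitted ("baseline") and with each
day's covariance determinant clamped to the day's minimum ("fixed
entropy").  Simulated renditions are scored with the predicted-age network
and overnight per-percentile shifts are regressed on percentile level.

This is a reduced-scale run (2 birds x 2 syllables); expect ~1 minute.
"""

import pandas as pd

import songdev
from songdev import entropy as en
from songdev import maturity as mt
from songdev.shifts import bin_and_quantile, fit_shift_lmm, overnight_shifts

SEED = 11
params = songdev.GroundTruthParams(
    n_birds=2, syllables_per_bird=2, k=6, renditions_per_day=2000,
    age_range=(60, 75), day_window=(7.2, 19.2), seed=SEED)
data = songdev.generate_dataset(params)

sims = []
for key, sub in data.groupby(["bird_id", "syllable_id"]):
    train, ev = songdev.split_dataset(sub, 0.2, seed=SEED)
    age_net = songdev.train_age_net(train, "pyramid", l2_weight=1e-4, seed=SEED)
    dev_net = songdev.train_dev_model(train, architecture="narrow64", seed=SEED,
                                      max_epochs=150, patience=15)
    q = en.sample_query_times(train, params.day_window, min_count=30)
    targets = en.daily_targets(dev_net, q)
    obs = ev[["bird_id", "syllable_id", "age_dph", "time_of_day_h", "day_index"]]
    for mode in ("baseline", "fixed_entropy"):
        sim = en.simulate_development(dev_net, obs, mode, seed=SEED + 1, targets=targets)
        sims.append(mt.attach_predicted_age(age_net, sim))
    print(f"trained + simulated {key}")

sim = pd.concat(sims, ignore_index=True)
records = overnight_shifts(bin_and_quantile(sim, min_n=30))
print(f"\n{len(records)} overnight shift records "
      f"({records.condition.value_counts().to_dict()})")
res = fit_shift_lmm(records, with_condition=True)
for name in ("Intercept", "percentile01", "cond", "percentile01:cond"):
    print(f"  {name:20s} {res.params[name]:+.3f} +/- {res.bse[name]:.3f}  "
          f"p = {res.pvalues[name]:.2e}")
slope_fixed = res.wald_linear_combo({"percentile01": 1, "percentile01:cond": 1})
print(f"\nbaseline percentile slope: {res.params['percentile01']:+.3f} days "
      f"(p = {res.pvalues['percentile01']:.3f})")
print(f"fixed-entropy net slope:   {slope_fixed[0]:+.3f} days (p = {slope_fixed[2]:.3f})")
print("\nReading: in baseline simulations the low maturity percentiles regress")
print("overnight and high percentiles progress (positive slope), purely because")
print("mornings are more variable than evenings. Clamping entropy within each")
print("day -- without touching the mean or the allocation of variation --")
print("eliminates the quantile dependence.")
print("\n(With only 2 birds the small-sample t inference here is very")
print("conservative; the 4-bird configuration in the test suite gives the")
print("same pattern with a clearly significant baseline slope.)")
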