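"""Generate a small synthetic developmental corpus and inspect its structure.

Builds two syllables' worth of renditions over ten days, prints per-day
latent centroid progress (the cluster drifts along a line in latent space)
and the morning-vs-evening sample entropy contrast the generator encodes.
"""

import numpy as np

import songdev
from songdev.synthetic import latent_columns

params = songdev.GroundTruthParams(
    n_birds=1, syllables_per_bird=2, k=6,
    renditions_per_day=400, age_range=(60, 70), seed=1,
)
data = songdev.generate_dataset(params)
zc = latent_columns(data)
print(f"corpus: {len(data)} renditions, {data.syllable_id.nunique()} syllables, "
      f"days {data.day_index.min()}-{data.day_index.max()}")

one = data[data.syllable_id == "b00_s00"]
print("\nday  centroid-progress  morning-logdet  evening-logdet")
for day, sub in one.groupby("day_index"):
    mo = sub[sub.time_of_day_h < 14][zc].to_numpy()
    ev = sub[sub.time_of_day_h >= 14][zc].to_numpy()
    prog = np.linalg.norm(sub[zc].mean() - one[one.day_index == 60][zc].mean())
    print(f"{day}   {prog:17.2f}  {np.linalg.slogdet(np.cov(mo.T))[1]:14.2f} "
          f"{np.linalg.slogdet(np.cov(ev.T))[1]:15.2f}")

print("\nThe centroid advances smoothly across days (development) while the")
print("morning sample covariance log-determinant exceeds the evening one on")
print("every day: variability contracts over each day of practice.")
print(f"\nTrue entropy at 65 dph: morning {songdev.true_entropy_at(params, 65.3, 8.0):.3f} "
      f"vs evening {songdev.true_entropy_at(params, 65.8, 20.0):.3f} nats")
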