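"""Quantify chosen-value coding with sliding-window regression.

For every 10 ms bin of the choice epoch, chosen value is regressed onto
the smoothed firing rate; the coefficient of partial determination (CPD)
is the fraction of rate variance uniquely explained by value.  A
permutation null (value shuffled across trials) gives the chance level.
"""

import numpy as np

from nts.cpd import cohort_cpd, permutation_null, population_cpd, significant_fraction
from nts.synthetic import GeneratorConfig, generate_dataset

cfg = GeneratorConfig(
    n_neurons={"OFC": 30}, n_trials=250, coding_profile="sustained",
    epochs={"choice_on": (0.0, 1.0)}, seed=4,
)
ds, _ = generate_dataset(cfg)

series = cohort_cpd(ds, "choice_on")
pop = population_cpd(list(series.values()))
null = permutation_null(ds, "choice_on", n_perm=500, seed=4)
frac = significant_fraction(list(series.values()))

t = next(iter(series.values())).times
peak = int(np.argmax(pop))
print(f"population CPD peaks at {100*pop[peak]:.1f}% at t = {t[peak]*1000:.0f} ms "
      f"after choice onset")
print(f"permutation null level = {100*null.level:.2f}% "
      f"(CPD expected by chance)")
print(f"fraction of bins above the null: {np.mean(pop > null.level):.2f} "
      f"(coding starts 100 ms after choice onset by construction)")
print(f"fraction of neurons individually significant at the peak: {frac[peak]:.2f}")
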