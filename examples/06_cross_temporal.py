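"""Ask whether the same neurons code value at choice and at outcome.

Chosen-value coefficients are computed separately on odd and even trials;
population coefficient vectors at every pair of time points are
cross-correlated across neurons.  Sustained codes correlate far off the
diagonal (choice patterns persist into reward); transient codes do not.
2-D cluster permutation tests mark significant regions.
"""

from nts import crosstemporal as xt
from nts.synthetic import GeneratorConfig, generate_dataset

for profile in ("sustained", "transient"):
    cfg = GeneratorConfig(
        n_neurons={"OFC": 60}, n_trials=240, coding_profile=profile,
        epochs={"choice_on": (0.0, 1.0), "reward_on": (-1.0, 1.0)}, seed=6,
    )
    ds, _ = generate_dataset(cfg)
    split = xt.split_half_coefficients(ds)
    n_rew = len(split.times["reward_on"])
    # the second after reward onset, trimming half the 100 ms smoothing
    # kernel so choice-epoch bleed across reward onset is not counted
    post = slice(n_rew // 2 + 5, n_rew)
    ctm = xt.cross_correlate(split, "choice_on", "reward_on", None, post)
    ctm = xt.cluster_test_2d(ctm, n_perm=400, seed=6)
    sig = [c for c in ctm.clusters if c.corrected_p < 0.05]
    area = max((c.area for c in sig), default=0)
    bridges = area > 0.05 * ctm.matrix.size  # a substantial block, not a speck
    print(f"{profile:10s}: mean choice-to-postreward r = {ctm.matrix.mean():+.3f}; "
          f"largest significant cluster = {area} px of {ctm.matrix.size} "
          f"({'bridges choice and outcome' if bridges else 'no cross-epoch code'})")
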