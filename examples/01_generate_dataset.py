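"""Generate a synthetic cohort with known ground truth and look inside.

Each neuron is an OU-modulated Poisson process: its resting rate wanders
with a private correlation time tau (the intrinsic timescale), and its
choice/reward-epoch rate can carry a chosen-value signal whose strength is
rank-linked to tau.
"""

from nts.synthetic import GeneratorConfig, generate_dataset

cfg = GeneratorConfig(
    n_neurons={"DLPFC": 5, "OFC": 5, "ACC": 5},
    n_trials=200,
    rho_target=0.5,            # rank corr between log tau and coding strength
    coding_profile="sustained",
    seed=1,
)
ds, truth = generate_dataset(cfg)

print(f"neurons: {len(ds.neurons)}, trials: {len(ds.trials)}, spikes: {len(ds.spikes)}")
print("\nground truth (first rows):")
print(truth[["neuron_id", "area", "tau_true", "baseline_rate", "value_beta_choice"]]
      .head(5).round(3).to_string(index=False))
print(
    "\ntau_true is the OU correlation time in seconds (the quantity the ACF"
    "\nanalysis must recover); value_beta_choice is the rate change per unit"
    "\nof chosen value during the choice epoch, in spikes/s."
)
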