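# nts — intrinsic neural timescales and value-coding statistics

`nts` is a Python library for a question that recurs in primate
prefrontal electrophysiology: **does a neuron's resting temporal
stability predict its role in value-guided choice?**  It implements the
full analysis chain on trial-aligned spike data —

1. **Intrinsic timescale estimation.**  The 1 s pre-trial fixation epoch
   is cut into twenty 50 ms bins; the across-trial Pearson correlation of
   spike counts between bins, collapsed over lag kΔ, is fitted with an
   exponential decay

   R(kΔ) = A · ( exp(−kΔ/τ) + B ),

   where τ is the neuron's intrinsic timescale, A the amplitude and B the
   offset contributed by timescales too slow to resolve.  Fitting starts
   at the largest drop between consecutive lags (excluding the
   refractoriness-depressed first lag), and objective criteria screen out
   neurons with low rates, no early decline, silent bins, degenerate
   signs or poor fits.  A sliding Kruskal–Wallis filter can restrict
   analysis to the longest run of trials without rate drift, and a
   hierarchical (random-effects) EM fit shrinks noisy per-neuron
   (log τ, A, B) toward a per-area multivariate Gaussian.

2. **Value-coding strength.**  Chosen value (benefit − cost) is
   regressed onto the smoothed firing rate in sliding 10 ms bins; the
   **coefficient of partial determination**

   CPD(X) = (SSE_reduced(X) − SSE_full) / SSE_reduced(X)

   measures the variance uniquely explained by a regressor, with a
   trial-shuffle permutation null fixing the chance level.

3. **Linking the two.**  Median splits of τ with 1-D cluster-based
   permutation tests across time, rank correlation between τ and CPD at
   the population-peak bin, multiple regression with rate/area controls,
   Bartlett and Kruskal–Wallis tests on log τ across areas, and a
   τ-sorted, neuron-smoothed display matrix.

4. **Cross-temporal pattern analysis.**  Split-half (odd/even trials)
   population coefficient vectors are cross-correlated across all time
   pairs; 2-D cluster permutation tests and Fisher r-to-Z group
   comparisons distinguish transient, sustained and reactivation
   population codes — e.g. whether the *same* neurons carry chosen value
   from choice through reward delivery.

Because real recordings ship without ground truth, the package includes a
first-class **synthetic generator**: doubly stochastic Poisson neurons
whose rate follows an Ornstein–Uhlenbeck process with a known correlation
time τ (giving an exponential count ACF by construction), plus per-trial
value modulation whose strength can be rank-linked to τ through a
Gaussian copula.  Every downstream stage is validated as parameter
recovery against this generator.

## Worked example

`examples/05_tau_cpd_link.py` generates 150 neurons (400 trials) with a
rank link of 0.5 between log τ and coding strength, then asks whether the
analyses see it:

```
high-vs-low tau cluster: 93 consecutive bins, corrected p = 0.0005 (significant at 0.05)
Spearman(tau, CPD at peak bin 47) = 0.538, 95% CI [0.413, 0.643] (generator rank link = 0.5)
log-tau coefficient controlling for rate and area: 2.352 [1.788, 2.917], p = 9.5e-14
display matrix: 150 neurons sorted by tau, bottom-quartile mean CPD 2.98% vs top-quartile 13.33%
```

Reading: high-τ neurons carry significantly more chosen-value variance
than low-τ neurons over a 930 ms run of the choice epoch; the rank
correlation recovers the generator's 0.5 link; and the effect survives
controlling for firing rate and area.  The other examples cover dataset
generation, timescale fitting, hierarchical shrinkage, CPD nulls, and
cross-temporal taxonomy — each prints a few numbers and what they mean.

A thin CLI wraps the two shell-level entry points:

```bash
nts generate --config generator.yaml --out data/ --seed 1
nts run --config pipeline.yaml          # full pipeline -> report.json
```

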