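# Methods

This note documents the models, conventions and numerical choices behind
`nts`, in the order data flow through the package.

## Synthetic spike data

The generator produces a doubly stochastic (Cox) spike process per
neuron.  Within each trial and epoch the instantaneous rate is

    lambda(t) = max(0, r0 + c·trial_index + x(t) + beta_e · (v − v̄) · g(t))

with baseline `r0` (spikes/s), optional linear drift `c` (spikes/s per
trial), a stationary Ornstein–Uhlenbeck process `x(t)` with correlation
time `tau_true` and marginal SD `rate_cv · r0`, and a chosen-value term
gated by the neuron's coding profile `g(t)` (none / transient / sustained
/ reactivation; windows are listed in `synthetic.PROFILE_WINDOWS`).
Spikes are a Poisson process given the rate, discretised piecewise-
constant on a `dt = 5 ms` grid (exact AR(1) discretisation of the OU
part).  The OU state is re-initialised from its stationary distribution
on every trial, so trials are exchangeable — the assumption behind the
across-trial ACF estimator; a carry-over switch exists for stressing the
stationarity filter.

An OU-modulated Poisson process was chosen because it is the minimal
model whose spike-count autocorrelation is exactly a single exponential
in the lag at the OU correlation time (the covariance of bin counts at
center distance L is proportional to exp(−L/τ)), i.e. exactly the decay
law the estimators assume, with B ≈ 0.  Rectification of the rate at
zero mildly damps the ACF; recovery tolerances absorb this.

**Default parameters** (chosen once as a realistic, estimable regime and
used by the recovery tests):

| parameter | default | meaning |
|---|---|---|
| `tau_log_mean`, `tau_log_sd` | log 0.22, 0.4 | log-normal τ, ~100–500 ms |
| `rate_log_mean`, `rate_log_sd` | log 15, 0.3 | baseline spikes/s |
| `rate_cv` | 1.2 | OU SD / baseline |
| `benefit_levels` × `cost_levels` | 1–4 × 0–2 | chosen value = benefit − cost |
| `beta_log_mean`, `beta_log_sd` | log 0.25, 0.8 | coding strength (see below) |
| `n_trials` | 400 | completed trials per session |

The baseline/modulation scale matters: with markedly weaker rate
modulation the 500-trial count ACF has amplitudes of a few hundredths,
the "largest consecutive drop" start rule fires on late-lag noise (late
lags average few bin pairs), and most neurons fail the decline criterion.
The default regime gives lag-1 autocorrelations of ~0.1–0.3, comparable
to well-isolated cortical units.

**Coding strength and the τ link.**  "Strength" is defined as a
standardized effect size: the rate shift per SD of chosen value, in units
of that neuron's own trial-to-trial rate-noise SD (Poisson + OU at 100 ms
resolution; `_rate_noise_sd`).  Strength magnitudes are log-normal and
linked to log τ by a Gaussian copula whose underlying Pearson correlation
is `2 sin(π ρ_s/6)`, so the *rank* correlation equals `rho_target`
exactly.  Defining the link on standardized strength (rather than raw
spikes/s slopes) makes the realized per-neuron CPD rank-follow the link;
a raw-slope link is structurally attenuated because CPD also depends on
each neuron's noise level.  Slopes are capped at `2.2 · r0 / max|v − v̄|`
so tail draws cannot drive the deterministic rate negative for most of an
epoch; the cap is monotone and touches only extreme draws.

All randomness descends from a single integer seed through
`numpy.random.SeedSequence` spawning; identical config + seed reproduce
datasets byte for byte.

## Timescale estimation

Counts: twenty successive 50 ms bins of the 1 s fixation epoch,
half-open `[left, right)` bins (a spike exactly at the window end is
excluded; documented because the convention is otherwise ambiguous).
The 20×20 across-trial Pearson matrix collapses to the lag ACF by
unweighted averaging of the (20−k) entries at lag k, NaN (zero-variance)
cells excluded.

**Fit.**  `R(kΔ) = A(exp(−kΔ/τ)+B)` by bounded trust-region least
squares, τ ∈ [1 ms, 10 s], 8 deterministic multi-starts log-spaced in τ
(the objective is multimodal on short windows).  The fit begins at the
lag where the largest consecutive-lag reduction lands, excluding the
refractoriness-depressed plateau.  B is bounded to [0, 2] by default: B
represents autocorrelation from components slower than the 950 ms lag
window and is non-negative by construction; allowing large negative B
lets a slow exponential with a spurious negative floor mimic a fast
decay, which destabilises τ badly (cohort pilots: Spearman with ground
truth 0.72 → 0.90 after bounding).

**Inclusion screen**, in order: fixation rate > 1 Hz; the largest drop
must land within the first 250 ms of lags (operationalising "decline in
the first 250 ms" with the same drop statistic as the start rule); no
50 ms bin silent across all trials (profiles with >25% undefined
correlation cells fall in the same bucket); amplitude A must be positive
(a strict mode excluding A>0 ∧ B>0 is available but non-default, since
ordinary decaying fits have exactly that signature); fitted-window
r² ≥ 0.2.  The r² screen is the automated stand-in for manual curation
of non-exponential ACFs; 0.2 is configurable.

**Stationarity filter.**  Sliding 100-trial windows of fixation counts,
each split into 4×25 successive groups and Kruskal–Wallis tested; a
window passes at p > 0.005 (p := 1 on all-constant data).  Maximal runs
of consecutive passing windows are merged — a run of starts [s0, s1]
covers trials [s0, s1+99] — and the longest covered interval is
selected.  This is the reading under which a mid-session rate step
confines the selection to one side; note KW at this threshold cannot
flag a window with ≲12 contaminated trials (measured for a 3× step), so
the selection may overhang a step by that many trials.  Sessions under
100 trials pass through flagged; if every window fails, the least
non-stationary window is returned with a warning.

**Hierarchical EM.**  Included neurons' windowed ACFs (starting, by
convention of this stage, at the *first* consecutive reduction — kept
deliberately distinct from the single-neuron largest-drop rule;
`start_rule` unifies them) are modelled as the exponential curve plus
i.i.d. Gaussian noise with per-neuron variance, with θ = (log τ, A, B)
drawn from a population Gaussian N(μ, Σ).  The E-step computes each
neuron's MAP by penalised least squares with a Gauss–Newton (Laplace)
posterior covariance; the M-step updates μ, Σ from posterior means plus
covariances and the noise variances from residuals.  B is free in
[−2, 2] here — the Gaussian prior regularises it smoothly, whereas a
zero floor piles estimates on the boundary and biases τ down by ~0.15
log units.  Convergence is tracked by a variational lower-bound proxy
(Gaussian q at the Laplace point); because the E-step is approximate,
strict monotonicity is not guaranteed, so the loop stops and reverts to
the previous iterate the moment the proxy decreases — the reported trace
is therefore non-decreasing.  Σ is ridge-regularised if its condition
number exceeds 1e10.  Initialisation: per-neuron LS fits; μ, Σ from
their median and MAD.

## Value-coding statistics

Rates are spikes/s in a 100 ms boxcar centred on each 10 ms bin
(truncated and width-renormalised at epoch edges); the bin grid is from
the analysis convention, the kernel an explicit package choice.  Per bin,
ordinary least squares of rate on the design (intercept + chosen value +
declared nuisance columns; the design is configuration-driven rather
than a hard-coded task model).  CPD is the partial R² of the regressor;
signed effects are t statistics (Z) with t-distribution p-values.
Collinear or constant designs raise errors naming the offending columns.

**Permutation null.**  The regressor of interest is shuffled across
trials within session, n_perm = 1000 by default.  The dashed-line null
level per area is, by default, the permutation-calibrated bound for the
population-mean CPD curve: grand mean of the permuted population mean
plus 1.96 × its across-permutation SD (averaged over bins).  Under a
no-coding generator the observed population curve then stays below the
level in ≈97.5% of bins.  An alternative convention (per-neuron permuted
CPD averaged over permutations and time, across-neuron mean + 1.96 SEM)
is available as `method="neuron_sem"`; its margin reflects only neuron
heterogeneity, collapses for homogeneous synthetic cohorts, and is kept
for comparability rather than calibration.

## Group statistics

Median splits assign exact-median ties to "low".  The 1-D cluster test
forms per-bin pooled-variance two-sample t statistics, takes the longest
run of consecutive bins beyond the two-sided p < 0.01 threshold inside a
pre-specified window (choice onset → +1 s; reward onset → +1 s), and
builds the null from group-label shuffles (default 10 000), recording
each shuffle's longest run.  Corrected p = (r+1)/(n_perm+1); the
0.05/0.01 flags use the 97.5th/99.5th null percentiles.  The rank
correlation uses the bin of the population-average CPD peak (earliest
bin on ties), with a Fisher-transform 95% CI.  The multiple regression
is OLS of log CPD (floored at 1e−8) on log τ + log fixation rate + area
dummies.  Across-area tests run on log τ: Bartlett for dispersion,
Kruskal–Wallis for location; identical samples return statistic 0 / p 1.
The display matrix sorts neurons by ascending τ and smooths along the
neuron axis only with a Gaussian of SD 2 rows (FWHM ≈ 4.7; the SD is
authoritative), truncated at ±4 SD with reflected boundaries — a
treatment under which constants are unchanged and the grand mean is
conserved exactly.

## Cross-temporal analysis

Coefficients (Z) are computed separately on odd and even trials (parity
of `trial_index_in_session`); the matrix entry (t1, t2) is the
across-neuron Pearson correlation between one half's population vector
at t1 and the other half's at t2, averaged over both half assignments.
Pixels significant at the two-sided p < 0.01 correlation test (at
n_neurons) are thresholded; connected components under 4-adjacency
(8-adjacency optional) form clusters scored by pixel count.  The null
permutes neuron identity in the even half only, which breaks cross-half
pattern alignment while preserving each half's marginal time course; a
time-shuffle mode exists but is non-default.  Group comparisons use
Fisher r-to-Z pixel statistics with variances 1/(n−3) and a
group-label-shuffle null on the largest difference-cluster area.
Analysis blocks pair the 1 s choice epoch with the seconds before and
after reward onset; "bridging" blocks used in the profile-taxonomy tests
trim half the 100 ms rate kernel (5 bins) at the reward-onset edge,
because the centred boxcar otherwise carries post-reward coding into the
last pre-reward bins.

## What the recovery suite does and does not show

The acceptance-style tests measure, on generator cohorts: τ recovery
(200 neurons × 500 trials: rank correlation ≥ 0.8, median relative error
< 25%), hierarchical μ_logτ recovery within ±0.1 with a monotone EM
proxy, null calibration of the CPD level and of the cluster test's
false-positive rate (200 cohorts, n_perm = 1000), link detection at
rho_target = 0.5 with 400 neurons over 50 seeds (800-trial sessions —
comparable to multi-hundred-trial primate recordings — chosen so CPD
measurement noise does not materially attenuate the rank link),
cross-temporal taxonomy (80-neuron, 300-trial cohorts; 2-D cluster
finder verified against an independent flood-fill oracle), stationarity
retention/monotonicity (the drift grid uses `rate_cv = 0.5` so drift
competes against counting noise rather than OU noise), and the
exclusion screen on a 20% flat / 80% OU cohort.  Permutation counts in
these tests are scaled to 400–2000 where the defaults of 10 000 would
only sharpen p-values far below the decision threshold.

Passing these tests shows the estimators are consistent and calibrated
*under the generative assumptions*: exponential-ACF rate dynamics,
exchangeable trials, linear rate–value coding, Poisson spiking.  Real
recordings violate all of these to degrees the generator does not model
— bursting and refractoriness, non-exponential or multi-timescale ACFs,
nonlinear value tuning, noise correlations between simultaneously
recorded neurons (the split-half design guards the cross-temporal
analysis against these, but CPD itself is per-neuron), and slow
non-drift nonstationarities.  Recovery numbers here are therefore upper
bounds on what to expect from data.

## Known limitations

- Single-exponential fits only; two-timescale neurons are either
  excluded by the r² screen or summarised by a compromise τ.
- The hierarchical posterior is a Laplace approximation; no MCMC check.
- The permutation engines assume exchangeability of trials (1-D/CPD
  nulls) or neurons (2-D nulls) under the null; session-level structure
  beyond the within-session shuffling is not modelled.
- `epoch_counts` treats trial ids as globally unique across sessions.
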