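"""Synthetic trial-aligned spike data with known ground truth.

The generative model is a doubly stochastic (Cox) process: each neuron's
instantaneous rate is

    lambda(t) = max(0,  r0 + drift·trial + x(t) + beta_epoch·(v - v_mean)·g(t))

where ``x(t)`` is a stationary Ornstein–Uhlenbeck process with correlation
time ``tau_true`` and marginal SD ``rate_cv · r0``, re-initialised from its
stationary distribution on every trial (so trials are exchangeable), ``v``
is the trial's chosen value, and ``g(t)`` is a 0/1 gate determined by the
neuron's coding profile.  Spikes are drawn as an inhomogeneous Poisson
process given the rate (piecewise-constant on a fine ``dt`` grid).

An OU-modulated Poisson process is the minimal model whose spike-count
autocorrelation decays exponentially with lag at the OU correlation time,
which is exactly the structure the downstream timescale estimators assume.
Rectification of the rate at zero slightly damps and biases that
autocorrelation; recovery tolerances downstream allow for this.

Per-neuron timescales are log-normal; coding strength magnitudes are
log-normal and tied to log tau through a Gaussian copula so that their rank
correlation matches ``rho_target``.

Everything is reproducible: one integer seed determines the whole dataset.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .io_core import DEFAULT_EPOCHS, SessionDataset

PROFILES = ("none", "transient", "sustained", "reactivation")

#: Active coding windows per profile, seconds relative to each event.
#: ``transient``: a brief burst of value coding early in the choice epoch.
#: ``sustained``: from early choice continuously through 1 s post reward.
#: ``reactivation``: coding at choice and again at outcome, with no
#: bridging activity in the pre-reward second.
PROFILE_WINDOWS: Mapping[str, Mapping[str, tuple[float, float]]] = {
    "none": {},
    "transient": {"choice_on": (0.1, 0.5)},
    "sustained": {"choice_on": (0.1, 1.0), "reward_on": (-1.0, 1.0)},
    "reactivation": {"choice_on": (0.1, 0.5), "reward_on": (0.0, 0.5)},
}


class DegenerateSpecError(ValueError):
    """The deterministic part of the rate is negative most of the time."""


@dataclass
class NeuronSpec:
    """Ground-truth parameters of one simulated neuron."""

    neuron_id: str
    area: str
    baseline_rate: float  # spikes/s
    tau_true: float  # s, OU correlation time
    value_beta_choice: float = 0.0  # spikes/s per value unit, choice epoch
    value_beta_outcome: float = 0.0  # spikes/s per value unit, reward epoch
    coding_profile: str = "none"
    drift_slope: float = 0.0  # spikes/s per trial

    def __post_init__(self) -> None:
        if self.baseline_rate <= 0:
            raise ValueError("baseline_rate must be > 0")
        if self.tau_true <= 0:
            raise ValueError("tau_true must be > 0")
        if self.coding_profile not in PROFILES:
            raise ValueError(f"unknown coding_profile {self.coding_profile!r}")


@dataclass
class GeneratorConfig:
    """Cohort-level knobs of the generator.

    Defaults describe the regime the downstream estimators are designed
    for: timescales of 100–500 ms, baseline rates of a few spikes/s with
    rate fluctuations comparable to the baseline, a discrete cost–benefit
    value grid, and — when coding is enabled — strongly value-tuned neurons
    whose per-trial rate shift is of order one spike/s per value unit.
    """

    n_neurons: Mapping[str, int] = field(
        default_factory=lambda: {"DLPFC": 10, "OFC": 10, "ACC": 10}
    )
    n_trials: int = 400
    epochs: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_EPOCHS)
    )
    dt: float = 0.005  # s, rate-discretisation step
    # intrinsic timescale distribution: log tau ~ Normal(mean, sd)
    tau_log_mean: float = float(np.log(0.22))
    tau_log_sd: float = 0.4
    #: optional per-area overrides of tau_log_mean (e.g. to give ACC the
    #: longest timescales)
    area_tau_log_mean: Mapping[str, float] | None = None
    # baseline rate distribution: log r0 ~ Normal(mean, sd), spikes/s
    rate_log_mean: float = float(np.log(15.0))
    rate_log_sd: float = 0.3
    rate_cv: float = 1.2  # OU marginal SD as a fraction of baseline
    # chosen value = benefit - cost on a discrete grid, or continuous N(0,1)
    benefit_levels: tuple = (1, 2, 3, 4)
    cost_levels: tuple = (0, 1, 2)
    continuous_value: bool = False
    # coding strength: log standardized effect ~ Normal(mean, sd), rank-
    # linked to log tau with Spearman correlation rho_target (Gaussian
    # copula).  Strength is the per-trial rate shift per SD of chosen
    # value, in units of the neuron's own trial-to-trial rate-noise SD
    # (Poisson + OU, 100 ms resolution), so the realized coding strength
    # is comparable across neurons with different rates and timescales;
    # the absolute slope in spikes/s per value unit lands in the truth
    # table.  The default (median 0.25 noise-SDs, log-sd 0.8) emulates a
    # strongly value-tuned cohort with peak CPDs of a few percent up to
    # tens of percent.
    rho_target: float = 0.0
    beta_log_mean: float = float(np.log(0.25))
    beta_log_sd: float = 0.8
    beta_sign_prob: float = 0.5  # probability of a negative value slope
    effect_window: float = 0.1  # s, rate-noise resolution behind "strength"
    coding_profile: str = "sustained"
    coding_fraction: float = 1.0
    drift_slope: float = 0.0  # spikes/s per trial, applied to every neuron
    ou_carryover: bool = False  # carry OU state across trials (stress mode)
    incomplete_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not -1.0 <= self.rho_target <= 1.0:
            raise ValueError("rho_target must lie in [-1, 1]")
        if self.n_trials <= 0 or any(n <= 0 for n in self.n_neurons.values()):
            raise ValueError("all counts must be positive")
        if self.coding_profile not in PROFILES:
            raise ValueError(f"unknown coding_profile {self.coding_profile!r}")


# ---------------------------------------------------------------------------
# trial table


def make_trial_table(cfg: GeneratorConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = cfg.n_trials
    if cfg.continuous_value:
        benefit = rng.normal(0.0, 1.0, n)
        cost = np.zeros(n)
    else:
        benefit = rng.choice(cfg.benefit_levels, size=n).astype(float)
        cost = rng.choice(cfg.cost_levels, size=n).astype(float)
    completed = rng.random(n) >= cfg.incomplete_fraction
    return pd.DataFrame(
        {
            "session_id": "S1",
            "trial_id": np.arange(n, dtype=np.int64),
            "trial_index_in_session": np.arange(n, dtype=np.int64),
            "completed": completed,
            "chosen_value": benefit - cost,
            "chosen_benefit": benefit,
            "chosen_cost": cost,
        }
    )


# ---------------------------------------------------------------------------
# single-neuron simulation


def _ou_paths(
    n_trials: int,
    n_steps: int,
    tau: float,
    sigma: float,
    dt: float,
    rng: np.random.Generator,
    carryover: bool,
) -> np.ndarray:
    """Exact-discretisation stationary OU sample paths, (n_trials, n_steps)."""
    if sigma == 0:
        return np.zeros((n_trials, n_steps))
    alpha = np.exp(-dt / tau)
    step_sd = sigma * np.sqrt(1.0 - alpha**2)
    if carryover:
        e = step_sd * rng.standard_normal(n_trials * n_steps)
        x0 = sigma * rng.standard_normal()
        x, _ = lfilter([1.0], [1.0, -alpha], e, zi=np.array([alpha * x0]))
        return x.reshape(n_trials, n_steps)
    e = step_sd * rng.standard_normal((n_trials, n_steps))
    x0 = sigma * rng.standard_normal(n_trials)
    x, _ = lfilter([1.0], [1.0, -alpha], e, axis=1, zi=(alpha * x0)[:, None])
    return x


def _coding_gate(event: str, edges: np.ndarray, profile: str) -> np.ndarray:
    """0/1 gate per fine bin for the profile's active window in this epoch."""
    win = PROFILE_WINDOWS[profile].get(event)
    gate = np.zeros(len(edges) - 1)
    if win is None:
        return gate
    centers = 0.5 * (edges[:-1] + edges[1:])
    gate[(centers >= win[0]) & (centers < win[1])] = 1.0
    return gate


def simulate_neuron(
    spec: NeuronSpec,
    trials: pd.DataFrame,
    cfg: GeneratorConfig,
    rng: np.random.Generator | int,
) -> pd.DataFrame:
    """Simulate one neuron's spikes for every epoch and completed trial.

    Returns spike-table rows (neuron_id, trial_id, event, spike_time).
    Incomplete trials are simulated too (the neuron fired regardless); the
    ``completed`` flag lives in the trial table and filters downstream.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    sigma = cfg.rate_cv * spec.baseline_rate
    trial_idx = trials["trial_index_in_session"].to_numpy()
    values = trials["chosen_value"].to_numpy(dtype=float)
    v_c = values - values.mean()
    n_trials = len(trials)

    frames = []
    neg_frac_accum = []
    for event, (start, end) in cfg.epochs.items():
        n_steps = int(round((end - start) / cfg.dt))
        edges = start + cfg.dt * np.arange(n_steps + 1)
        gate = _coding_gate(event, edges, spec.coding_profile)
        beta = (
            spec.value_beta_choice
            if event == "choice_on"
            else spec.value_beta_outcome if event == "reward_on" else 0.0
        )
        det = (
            spec.baseline_rate
            + spec.drift_slope * trial_idx[:, None]
            + beta * v_c[:, None] * gate[None, :]
        )
        neg_frac_accum.append(np.mean(det < 0))
        x = _ou_paths(n_trials, n_steps, spec.tau_true, sigma, cfg.dt, rng, cfg.ou_carryover)
        lam = np.clip(det + x, 0.0, None)
        counts = rng.poisson(lam * cfg.dt)
        total = int(counts.sum())
        if total:
            flat = counts.ravel()
            nz = np.flatnonzero(flat)
            reps = flat[nz]
            lefts = edges[:-1][nz % n_steps]
            t_rows = trials["trial_id"].to_numpy()[nz // n_steps]
            spike_t = np.repeat(lefts, reps) + cfg.dt * rng.random(total)
            frames.append(
                pd.DataFrame(
                    {
                        "neuron_id": spec.neuron_id,
                        "trial_id": np.repeat(t_rows, reps),
                        "event": event,
                        "spike_time": spike_t,
                    }
                )
            )
    if np.mean(neg_frac_accum) > 0.5:
        raise DegenerateSpecError(
            f"neuron {spec.neuron_id}: deterministic rate negative on "
            f"{100 * np.mean(neg_frac_accum):.0f}% of time bins"
        )
    if not frames:
        return pd.DataFrame(columns=["neuron_id", "trial_id", "event", "spike_time"])
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# cohort generation


def _copula_strengths(
    log_tau_z: np.ndarray, cfg: GeneratorConfig, rng: np.random.Generator
) -> np.ndarray:
    """Standardized coding-strength magnitudes rank-correlated with log tau.

    ``log_tau_z`` are the standard-normal scores behind log tau.  The
    Pearson correlation of the underlying Gaussian pair is chosen so the
    rank (Spearman) correlation equals ``rho_target``:
    rho_pearson = 2 sin(pi * rho_s / 6).
    """
    rho_p = 2.0 * np.sin(np.pi * cfg.rho_target / 6.0)
    w = rng.standard_normal(len(log_tau_z))
    z2 = rho_p * log_tau_z + np.sqrt(max(0.0, 1.0 - rho_p**2)) * w
    return np.exp(cfg.beta_log_mean + cfg.beta_log_sd * z2)


def _rate_noise_sd(r0: np.ndarray, tau: np.ndarray, cfg: GeneratorConfig) -> np.ndarray:
    """Trial-to-trial SD of the rate estimate in an ``effect_window`` boxcar.

    Poisson counting noise contributes r0/w; the OU modulation contributes
    its marginal variance attenuated by averaging over the window,
    var_mean = 2 sigma^2 (tau/w)^2 (w/tau - 1 + exp(-w/tau)).
    """
    w = cfg.effect_window
    sigma2 = (cfg.rate_cv * r0) ** 2
    u = w / tau
    atten = 2.0 / u**2 * (u - 1.0 + np.exp(-u))
    return np.sqrt(r0 / w + sigma2 * atten)


def draw_neuron_specs(
    cfg: GeneratorConfig,
    rng: np.random.Generator,
    value_sd: float = 1.0,
    value_absmax: float | None = None,
) -> list[NeuronSpec]:
    """Draw per-neuron ground-truth parameters for a cohort.

    Coding slopes are capped at 2.2·baseline / ``value_absmax`` (max
    |v - mean v|): tail draws of the strength distribution would otherwise
    drive the deterministic rate negative for most of the epoch and trip
    the degenerate-spec guard, while at this cap the rate goes negative
    only in one value tail (rectification then silences the neuron there,
    as real value-coding neurons are).  The cap is monotone and affects
    only extreme draws, so the rank link between tau and strength survives.
    """
    specs: list[NeuronSpec] = []
    for area in cfg.n_neurons:
        n = cfg.n_neurons[area]
        mu = (
            cfg.area_tau_log_mean[area]
            if cfg.area_tau_log_mean is not None
            else cfg.tau_log_mean
        )
        z_tau = rng.standard_normal(n)
        tau = np.exp(mu + cfg.tau_log_sd * z_tau)
        r0 = np.exp(cfg.rate_log_mean + cfg.rate_log_sd * rng.standard_normal(n))
        strength = _copula_strengths(z_tau, cfg, rng)
        beta_mag = strength * _rate_noise_sd(r0, tau, cfg) / max(value_sd, 1e-12)
        if value_absmax:
            beta_mag = np.minimum(beta_mag, 2.2 * r0 / value_absmax)
        sign = np.where(rng.random(n) < cfg.beta_sign_prob, -1.0, 1.0)
        codes = rng.random(n) < cfg.coding_fraction
        for i in range(n):
            profile = cfg.coding_profile if codes[i] else "none"
            b = sign[i] * beta_mag[i] if profile != "none" else 0.0
            specs.append(
                NeuronSpec(
                    neuron_id=f"{area}_{i:03d}",
                    area=area,
                    baseline_rate=float(r0[i]),
                    tau_true=float(tau[i]),
                    value_beta_choice=float(b),
                    value_beta_outcome=float(b),
                    coding_profile=profile,
                    drift_slope=cfg.drift_slope,
                )
            )
    return specs


def generate_dataset(cfg: GeneratorConfig) -> tuple[SessionDataset, pd.DataFrame]:
    """Draw a full cohort and return (dataset, ground-truth table).

    The ground-truth table has one row per neuron: the drawn tau, baseline,
    value slopes and coding profile.  Identical config + seed reproduce the
    dataset byte for byte.
    """
    ss = np.random.SeedSequence(cfg.seed)
    s_design, s_specs, s_neurons = ss.spawn(3)
    trials = make_trial_table(cfg, np.random.default_rng(s_design))
    v = trials["chosen_value"].to_numpy(dtype=float)
    value_sd = float(v.std()) or 1.0
    value_absmax = float(np.max(np.abs(v - v.mean()))) or 1.0
    specs = draw_neuron_specs(
        cfg, np.random.default_rng(s_specs), value_sd=value_sd, value_absmax=value_absmax
    )
    child_seeds = s_neurons.spawn(len(specs))
    frames = [
        simulate_neuron(spec, trials, cfg, np.random.default_rng(child))
        for spec, child in zip(specs, child_seeds)
    ]
    spikes = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["neuron_id", "trial_id", "event", "spike_time"])
    )
    neurons = pd.DataFrame(
        {
            "neuron_id": [s.neuron_id for s in specs],
            "session_id": "S1",
            "area": [s.area for s in specs],
        }
    )
    truth = pd.DataFrame(
        {
            "neuron_id": [s.neuron_id for s in specs],
            "area": [s.area for s in specs],
            "tau_true": [s.tau_true for s in specs],
            "baseline_rate": [s.baseline_rate for s in specs],
            "value_beta_choice": [s.value_beta_choice for s in specs],
            "value_beta_outcome": [s.value_beta_outcome for s in specs],
            "coding_profile": [s.coding_profile for s in specs],
            "drift_slope": [s.drift_slope for s in specs],
        }
    )
    ds = SessionDataset(
        spikes=spikes, trials=trials, neurons=neurons, epochs=dict(cfg.epochs)
    )
    return ds, truth


def config_from_dict(d: Mapping) -> GeneratorConfig:
    """Build a GeneratorConfig from a (YAML-friendly) mapping."""
    known = {f.name for f in dataclasses.fields(GeneratorConfig)}
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown generator options: {sorted(unknown)}")
    d = dict(d)
    for tup_key in ("benefit_levels", "cost_levels"):
        if tup_key in d:
            d[tup_key] = tuple(d[tup_key])
    return GeneratorConfig(**d)
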