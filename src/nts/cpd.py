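"""Sliding-bin regression of task variables onto firing rate.

For every 10 ms time bin, the trial-wise firing rate (spikes/s in a 100 ms
boxcar centred on the bin) is regressed on a design matrix of task
variables (chosen value, optionally its benefit and cost components and
named nuisance regressors, plus an implicit intercept).  The contribution
of one regressor X is summarised by its coefficient of partial
determination,

    CPD(X) = (SSE_reduced(X) - SSE_full) / SSE_reduced(X),

the fraction of residual variance uniquely explained by X; signed effects
are carried as the coefficient Z (= beta / SE) with a t-distribution
p-value.

Because CPD is positive by construction, its chance level is assessed by a
permutation scheme: the regressor of interest is shuffled across trials
(within session), the permuted CPD averaged over permutations per neuron
and time bin, and the population null level set at the upper bound of the
95% confidence interval of the time-pooled per-neuron averages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_core import SessionDataset, epoch_counts_all


class RankDeficientDesignError(ValueError):
    pass


@dataclass
class DesignInfo:
    """Validated design matrix: trials × (1 + regressors), intercept first."""

    matrix: np.ndarray
    names: list[str]  # regressor names, excluding the intercept
    condition_number: float

    @property
    def n_params(self) -> int:
        return self.matrix.shape[1]

    def column(self, name: str) -> int:
        return 1 + self.names.index(name)


@dataclass
class CPDSeries:
    neuron_id: str
    event: str
    times: np.ndarray  # bin centres, s relative to the event
    regressors: list[str]
    cpd: np.ndarray  # bins × regressors, in [0, 1]
    z: np.ndarray  # bins × regressors signed coefficient Z
    p: np.ndarray  # bins × regressors two-sided p

    def for_regressor(self, name: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        j = self.regressors.index(name)
        return self.cpd[:, j], self.z[:, j], self.p[:, j]


@dataclass
class NullLevel:
    label: str
    regressor: str
    level: float  # scalar null CPD (upper 95% CI bound across neurons)
    n_permutations: int
    per_neuron: np.ndarray  # time-pooled mean permuted CPD per neuron


# ---------------------------------------------------------------------------
# design construction


def build_design(
    trials: pd.DataFrame, regressors: tuple[str, ...] = ("chosen_value",)
) -> DesignInfo:
    """Design matrix from completed-trial columns, intercept included.

    Raises on constant or collinear columns (naming the offenders).
    """
    cols = []
    for name in regressors:
        x = trials[name].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            raise RankDeficientDesignError(f"regressor {name!r} is constant across trials")
        cols.append(x)
    x_mat = np.column_stack([np.ones(len(trials))] + cols)
    rank = np.linalg.matrix_rank(x_mat)
    if rank < x_mat.shape[1]:
        # find a minimal collinear set by greedy elimination
        bad = []
        for j in range(1, x_mat.shape[1]):
            others = np.delete(x_mat, j, axis=1)
            if np.linalg.matrix_rank(others) == rank:
                bad.append(regressors[j - 1])
        raise RankDeficientDesignError(
            f"design is rank-deficient; collinear columns: {bad or list(regressors)}"
        )
    cond = float(np.linalg.cond(x_mat))
    return DesignInfo(matrix=x_mat, names=list(regressors), condition_number=cond)


# ---------------------------------------------------------------------------
# rate estimation


def binned_rates_all(
    ds: SessionDataset,
    event: str,
    window: tuple[float, float] | None = None,
    bin_ms: float = 10.0,
    kernel_ms: float = 100.0,
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Smoothed firing rates for every neuron: trials × bins, spikes/s.

    The rate at a bin centre c counts spikes in [c - k/2, c + k/2) and
    divides by the covered width; the boxcar is truncated (and the width
    renormalised) at the epoch edges.  Returns (rates per neuron, bin
    centres).
    """
    if window is None:
        window = ds.epochs[event]
    start, end = window
    fine = bin_ms / 2000.0  # s; fine grid so the boxcar edges land on it
    n_fine = int(round((end - start) / fine))
    counts = epoch_counts_all(ds, event, window, fine)
    step = int(round(bin_ms / 1000.0 / fine))  # fine bins per output bin (=2)
    half = int(round(kernel_ms / 2000.0 / fine))  # fine bins per half kernel
    n_bins = n_fine // step
    centers_idx = step * np.arange(n_bins) + step // 2  # fine index of bin centre
    lo = np.clip(centers_idx - half, 0, n_fine)
    hi = np.clip(centers_idx + half, 0, n_fine)
    width_s = (hi - lo) * fine
    times = start + fine * centers_idx
    out = {}
    for nid, c in counts.items():
        csum = np.concatenate(
            [np.zeros((c.shape[0], 1)), np.cumsum(c, axis=1)], axis=1
        )
        out[nid] = (csum[:, hi] - csum[:, lo]) / width_s
    return out, times


# ---------------------------------------------------------------------------
# OLS + CPD core


def _ols_cpd(y: np.ndarray, design: DesignInfo) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised per-bin OLS: CPD, Z and p for each named regressor.

    ``y`` is trials × bins; returns three bins × regressors arrays.
    """
    x = design.matrix
    n, p = x.shape
    xtx = x.T @ x
    xty = x.T @ y
    beta = np.linalg.solve(xtx, xty)  # p × bins
    yty = np.einsum("ij,ij->j", y, y)
    sse_full = np.maximum(yty - np.einsum("pj,pj->j", beta, xty), 0.0)
    dof = n - p
    s2 = sse_full / max(dof, 1)
    xtx_inv = np.linalg.inv(xtx)

    n_reg = len(design.names)
    cpd = np.zeros((y.shape[1], n_reg))
    zmat = np.zeros_like(cpd)
    pmat = np.ones_like(cpd)
    for j, name in enumerate(design.names):
        col = design.column(name)
        xr = np.delete(x, col, axis=1)
        beta_r = np.linalg.solve(xr.T @ xr, xr.T @ y)
        sse_red = np.maximum(yty - np.einsum("pj,pj->j", beta_r, xr.T @ y), 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            c = (sse_red - sse_full) / sse_red
        cpd[:, j] = np.clip(np.nan_to_num(c), 0.0, 1.0)
        se = np.sqrt(np.maximum(s2 * xtx_inv[col, col], 1e-300))
        z = beta[col] / se
        zmat[:, j] = z
        if dof > 0:
            pmat[:, j] = 2.0 * stats.t.sf(np.abs(z), dof)
    return cpd, zmat, pmat


def binwise_regression(
    rates: np.ndarray,
    design: DesignInfo,
    times: np.ndarray,
    neuron_id: str = "",
    event: str = "",
) -> CPDSeries:
    """CPD / Z / p time series for one neuron's smoothed rates."""
    rates = np.asarray(rates, dtype=float)
    if rates.shape[0] < 10:
        raise ValueError("need >= 10 completed trials for binwise regression")
    if rates.shape[0] != design.matrix.shape[0]:
        raise ValueError("rates and design matrix disagree on trial count")
    cpd, z, p = _ols_cpd(rates, design)
    return CPDSeries(
        neuron_id=neuron_id, event=event, times=np.asarray(times),
        regressors=list(design.names), cpd=cpd, z=z, p=p,
    )


def cohort_cpd(
    ds: SessionDataset,
    event: str,
    window: tuple[float, float] | None = None,
    regressors: tuple[str, ...] = ("chosen_value",),
    bin_ms: float = 10.0,
    kernel_ms: float = 100.0,
    neuron_ids: list[str] | None = None,
) -> dict[str, CPDSeries]:
    """Binwise regression for every (or selected) neuron of a dataset."""
    trials = ds.completed_trials()
    design = build_design(trials, regressors)
    rates, times = binned_rates_all(ds, event, window, bin_ms, kernel_ms)
    ids = neuron_ids if neuron_ids is not None else list(rates)
    return {
        nid: binwise_regression(rates[nid], design, times, neuron_id=nid, event=event)
        for nid in ids
    }


# ---------------------------------------------------------------------------
# permutation null


def _permuted_cpd(
    y: np.ndarray,
    design: DesignInfo,
    regressor: str,
    perm_x: np.ndarray,
) -> np.ndarray:
    """Permuted CPD for one neuron: n_perm × bins.

    ``perm_x`` is n_perm × trials: the shuffled regressor of interest; all
    other columns stay fixed.  Batched normal equations keep this fast.
    """
    x = design.matrix
    n, p = x.shape
    col = design.column(regressor)
    m = perm_x.shape[0]

    xtx = x.T @ x
    xty = x.T @ y  # p × bins
    yty = np.einsum("ij,ij->j", y, y)

    xr = np.delete(x, col, axis=1)
    beta_r = np.linalg.solve(xr.T @ xr, xr.T @ y)
    sse_red = np.maximum(yty - np.einsum("pj,pj->j", beta_r, xr.T @ y), 0.0)

    cross = perm_x @ x  # m × p ; entry [., k] = x_perm . x[:, k]
    s2 = float(np.sum(x[:, col] ** 2))  # permutation-invariant
    t = np.broadcast_to(xtx, (m, p, p)).copy()
    t[:, col, :] = cross
    t[:, :, col] = cross
    t[:, col, col] = s2

    xty_b = np.broadcast_to(xty, (m, p, y.shape[1])).copy()
    xty_b[:, col, :] = perm_x @ y

    beta = np.linalg.solve(t, xty_b)  # m × p × bins
    sse_full = np.maximum(yty[None, :] - np.einsum("mpb,mpb->mb", beta, xty_b), 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        cpd = (sse_red[None, :] - sse_full) / sse_red[None, :]
    return np.clip(np.nan_to_num(cpd), 0.0, 1.0)


def permutation_null(
    ds: SessionDataset,
    event: str,
    window: tuple[float, float] | None = None,
    regressors: tuple[str, ...] = ("chosen_value",),
    regressor: str = "chosen_value",
    n_perm: int = 1000,
    seed: int = 0,
    bin_ms: float = 10.0,
    kernel_ms: float = 100.0,
    neuron_ids: list[str] | None = None,
    label: str = "",
    method: str = "population",
) -> NullLevel:
    """Population null CPD level for one regressor of interest.

    The regressor is shuffled across trials within each session and the
    permuted CPD computed per neuron, permutation and bin.  Two
    conventions turn this into the single dashed-line level per area:

    * ``population`` (default) — the level is the permutation-calibrated
      upper bound for the *population-mean* CPD curve: grand mean of the
      permuted population-mean plus 1.96 times its across-permutation SD
      (averaged over bins).  Under a no-coding generator the observed
      population curve then stays below the level in ~97.5% of bins.
    * ``neuron_sem`` — per-neuron permuted CPD is averaged over
      permutations and pooled over bins, and the level is the
      across-neuron mean + 1.96 SEM of those time-pooled averages.  This
      margin reflects neuron heterogeneity only; for homogeneous cohorts
      it collapses onto the null mean and the observed (unaveraged)
      population curve fluctuates above it in roughly half the bins, so it
      is not a calibrated bound for the per-bin curve.
    """
    if n_perm < 100:
        warnings.warn("fewer than 100 permutations: null level will be unstable")
    trials = ds.completed_trials()
    design = build_design(trials, regressors)
    rng = np.random.default_rng(seed)

    sessions = trials["session_id"].to_numpy()
    base = design.matrix[:, design.column(regressor)]
    perm_x = np.empty((n_perm, len(trials)))
    for i in range(n_perm):
        xp = base.copy()
        for s in pd.unique(sessions):
            idx = np.flatnonzero(sessions == s)
            xp[idx] = xp[rng.permutation(idx)]
        perm_x[i] = xp

    rates, _ = binned_rates_all(ds, event, window, bin_ms, kernel_ms)
    ids = neuron_ids if neuron_ids is not None else list(rates)
    pop_sum = None  # per-permutation, per-bin sum of CPD over neurons
    pooled = np.empty(len(ids))
    for i, nid in enumerate(ids):
        c = _permuted_cpd(rates[nid], design, regressor, perm_x)
        pooled[i] = c.mean()
        pop_sum = c if pop_sum is None else pop_sum + c
    if method == "population":
        pop_mean = pop_sum / len(ids)  # n_perm × bins population-mean CPD
        level = float(
            pop_mean.mean() + 1.96 * pop_mean.std(axis=0, ddof=1).mean()
        )
    elif method == "neuron_sem":
        level = float(pooled.mean() + 1.96 * pooled.std(ddof=1) / np.sqrt(len(pooled)))
    else:
        raise ValueError(f"unknown null-level method {method!r}")
    return NullLevel(
        label=label, regressor=regressor, level=level,
        n_permutations=n_perm, per_neuron=pooled,
    )


# ---------------------------------------------------------------------------
# population summaries


def population_cpd(series: list[CPDSeries], regressor: str = "chosen_value") -> np.ndarray:
    """Across-neuron mean CPD per time bin."""
    return np.mean([s.for_regressor(regressor)[0] for s in series], axis=0)


def significant_fraction(
    series: list[CPDSeries],
    regressor: str = "chosen_value",
    alpha: float = 0.05,
    smooth_bins: int = 5,
) -> np.ndarray:
    """Per-bin fraction of neurons with p < alpha, boxcar-smoothed.

    The chance line is ``alpha`` itself.  Smoothing runs over
    ``smooth_bins`` successive bins with edge renormalisation.
    """
    if not series:
        raise ValueError("need at least one CPD series")
    sig = np.array([s.for_regressor(regressor)[2] < alpha for s in series], dtype=float)
    frac = sig.mean(axis=0)
    if smooth_bins > 1:
        kern = np.ones(smooth_bins)
        frac = np.convolve(frac, kern, mode="same") / np.convolve(
            np.ones_like(frac), kern, mode="same"
        )
    return frac
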