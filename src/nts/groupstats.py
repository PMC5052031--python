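"""Linking resting timescales to value coding across neurons.

Tools for the cohort-level questions: do neurons with long resting
timescales carry stronger chosen-value signals?  Median splits of tau,
two-sample t statistics per time bin with cluster-based permutation
correction (longest run of consecutive supra-threshold bins against a
group-label-shuffle null), rank correlation between tau and CPD at the
population-peak bin, a multiple regression of log CPD on log tau
controlling for baseline rate and area, across-area dispersion/location
tests on log tau, and the tau-sorted display matrix with across-neuron
Gaussian smoothing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats


@dataclass
class ClusterTestResult:
    label: str
    t_values: np.ndarray  # per-bin two-sample t
    alpha_form: float
    cluster_length: int  # longest observed run of supra-threshold bins
    cluster_window: tuple[int, int] | None  # [start, end] bin indices, or None
    corrected_p: float
    null_quantiles: dict[str, float]
    n_permutations: int

    @property
    def significant_05(self) -> bool:
        return self.cluster_length > self.null_quantiles["97.5"]

    @property
    def significant_01(self) -> bool:
        return self.cluster_length > self.null_quantiles["99.5"]


@dataclass
class TauCpdLink:
    rho: float
    rho_ci: tuple[float, float]
    rho_p: float
    peak_bin: int
    degenerate: bool = False


# ---------------------------------------------------------------------------
# median split


def median_split(tau: pd.Series | np.ndarray, areas: pd.Series | None = None) -> np.ndarray:
    """Label neurons 'high'/'low' by tau relative to the median.

    Ties at the median go to 'low'.  When ``areas`` is given the split is
    performed within each area separately.
    """
    tau = np.asarray(tau, dtype=float)
    labels = np.empty(len(tau), dtype=object)
    if areas is not None:
        areas = np.asarray(areas)
        for a in pd.unique(areas):
            m = areas == a
            labels[m] = median_split(tau[m])
        return labels
    med = np.median(tau)
    labels[:] = "low"
    labels[tau > med] = "high"
    if not (labels == "high").any():
        warnings.warn("degenerate median split: no neuron above the median")
    return labels


# ---------------------------------------------------------------------------
# 1-D cluster-based permutation test


def _longest_run(mask: np.ndarray) -> tuple[int, int, int]:
    """(length, start, end) of the longest True run in a 1-D mask."""
    best_len = best_start = 0
    cur_len = cur_start = 0
    for i, v in enumerate(mask):
        if v:
            if cur_len == 0:
                cur_start = i
            cur_len += 1
            if cur_len > best_len:
                best_len, best_start = cur_len, cur_start
        else:
            cur_len = 0
    return best_len, best_start, best_start + best_len - 1


def _longest_runs_2d(mask: np.ndarray) -> np.ndarray:
    """Longest True run per row of a 2-D boolean array (vectorised)."""
    m, n = mask.shape
    padded = np.zeros((m, n + 2), dtype=bool)
    padded[:, 1:-1] = mask
    d = np.diff(padded.astype(np.int8), axis=1)
    out = np.zeros(m, dtype=np.int64)
    rows, starts = np.nonzero(d == 1)
    _, ends = np.nonzero(d == -1)
    lengths = ends - starts
    if len(rows):
        np.maximum.at(out, rows, lengths)
    return out


def _two_sample_t(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pooled-variance two-sample t per column; a, b are group × bins."""
    na, nb = a.shape[0], b.shape[0]
    ma, mb = a.mean(axis=0), b.mean(axis=0)
    va, vb = a.var(axis=0, ddof=1), b.var(axis=0, ddof=1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    denom = np.sqrt(np.maximum(sp2 * (1.0 / na + 1.0 / nb), 1e-300))
    return (ma - mb) / denom


def cluster_test_1d(
    group_a: np.ndarray,
    group_b: np.ndarray,
    window: tuple[int, int] | None = None,
    alpha_form: float = 0.01,
    n_perm: int = 10000,
    seed: int = 0,
    label: str = "",
) -> ClusterTestResult:
    """Cluster-corrected comparison of two groups' CPD time series.

    Inputs are neurons × bins arrays.  A two-sample t statistic is formed
    per bin; the observed statistic is the longest run of consecutive bins
    exceeding the (two-sided) cluster-forming threshold inside the
    pre-specified ``window`` (bin-index bounds, inclusive).  The null
    shuffles group labels ``n_perm`` times and records each permutation's
    longest run; corrected p = (r + 1) / (n_perm + 1), and the printed
    97.5/99.5 percentile rules give the 0.05/0.01 significance flags.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("each group needs at least 2 neurons")
    if a.shape[1] != b.shape[1]:
        raise ValueError("groups must share the time-bin grid")
    n_bins = a.shape[1]
    if window is None:
        window = (0, n_bins - 1)
    w0, w1 = window
    if not (0 <= w0 <= w1 < n_bins):
        raise ValueError(f"window {window} outside the data range [0, {n_bins - 1}]")

    na, nb = a.shape[0], b.shape[0]
    df = na + nb - 2
    t_crit = stats.t.ppf(1.0 - alpha_form / 2.0, df)
    t_obs = _two_sample_t(a, b)
    obs_len, s, e = _longest_run(np.abs(t_obs[w0 : w1 + 1]) > t_crit)
    cluster_window = (w0 + s, w0 + e) if obs_len else None

    data = np.vstack([a, b])[:, w0 : w1 + 1]
    n = na + nb
    rng = np.random.default_rng(seed)
    # vectorised label shuffles: group sums via 0/1 selection matrices
    sel = np.zeros((n_perm, n))
    for i in range(n_perm):
        sel[i, rng.permutation(n)[:na]] = 1.0
    tot = data.sum(axis=0)
    tot2 = (data**2).sum(axis=0)
    sa = sel @ data
    sa2 = sel @ data**2
    ma = sa / na
    mb = (tot - sa) / nb
    va = (sa2 - na * ma**2) / (na - 1)
    vb = ((tot2 - sa2) - nb * mb**2) / (nb - 1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / df
    with np.errstate(divide="ignore", invalid="ignore"):
        t_null = (ma - mb) / np.sqrt(np.maximum(sp2 * (1.0 / na + 1.0 / nb), 1e-300))
    null_lengths = _longest_runs_2d(np.abs(t_null) > t_crit)
    r = int(np.sum(null_lengths >= obs_len)) if obs_len else n_perm
    corrected_p = (r + 1) / (n_perm + 1)
    q = {
        "97.5": float(np.percentile(null_lengths, 97.5)),
        "99.5": float(np.percentile(null_lengths, 99.5)),
    }
    return ClusterTestResult(
        label=label, t_values=t_obs, alpha_form=alpha_form,
        cluster_length=int(obs_len), cluster_window=cluster_window,
        corrected_p=float(corrected_p), null_quantiles=q, n_permutations=n_perm,
    )


# ---------------------------------------------------------------------------
# rank correlation at the population-peak bin


def rank_corr_at_peak(
    tau: np.ndarray, cpd_matrix: np.ndarray, label: str = ""
) -> TauCpdLink:
    """Spearman correlation of tau with per-neuron CPD at the peak bin.

    The peak bin is the argmax of the across-neuron mean CPD (earliest bin
    on ties) — a population-level choice, never per neuron.  The 95% CI is
    by Fisher transform.
    """
    tau = np.asarray(tau, dtype=float)
    cpd_matrix = np.asarray(cpd_matrix, dtype=float)
    if len(tau) < 10:
        raise ValueError("need >= 10 neurons for the rank correlation")
    mean_curve = cpd_matrix.mean(axis=0)
    peak = int(np.argmax(mean_curve))
    x = cpd_matrix[:, peak]
    if np.ptp(x) == 0 or np.ptp(tau) == 0:
        return TauCpdLink(0.0, (0.0, 0.0), 1.0, peak, degenerate=True)
    rho, p = stats.spearmanr(tau, x)
    n = len(tau)
    z = np.arctanh(np.clip(rho, -0.999999, 0.999999))
    hw = 1.96 / np.sqrt(n - 3)
    ci = (float(np.tanh(z - hw)), float(np.tanh(z + hw)))
    return TauCpdLink(float(rho), ci, float(p), peak)


# ---------------------------------------------------------------------------
# multiple regression with area controls


def tau_cpd_regression(
    tau: np.ndarray,
    cpd_at_peak: np.ndarray,
    fixation_rate: np.ndarray,
    areas: np.ndarray,
    reference_area: str = "DLPFC",
    cpd_floor: float = 1e-8,
) -> pd.DataFrame:
    """OLS of log CPD on log tau + log rate + area dummies.

    Zero CPDs are floored at ``cpd_floor`` before the log.  Returns the
    coefficient table (coef, 95% CI, p) with ``log_tau`` as the row of
    interest.
    """
    y = np.log(np.maximum(np.asarray(cpd_at_peak, dtype=float), cpd_floor))
    areas = pd.Series(np.asarray(areas))
    dummies = pd.get_dummies(areas, prefix="area", dtype=float)
    ref = f"area_{reference_area}"
    if ref in dummies.columns:
        dummies = dummies.drop(columns=[ref])
    x = pd.DataFrame(
        {
            "log_tau": np.log(np.asarray(tau, dtype=float)),
            "log_rate": np.log(np.maximum(np.asarray(fixation_rate, dtype=float), 1e-12)),
        }
    )
    x = pd.concat([x, dummies.reset_index(drop=True)], axis=1)
    x = sm.add_constant(x)
    if np.linalg.matrix_rank(x.to_numpy()) < x.shape[1]:
        raise ValueError("collinear design (check area dummy coding)")
    fit = sm.OLS(y, x).fit()
    ci = fit.conf_int()
    return pd.DataFrame(
        {
            "coef": fit.params,
            "ci_low": ci[0],
            "ci_high": ci[1],
            "p": fit.pvalues,
        }
    )


# ---------------------------------------------------------------------------
# across-area dispersion and location tests


def area_dispersion_tests(tau: np.ndarray, areas: np.ndarray) -> dict:
    """Bartlett (variance) and Kruskal–Wallis (location) tests on log tau."""
    tau = np.asarray(tau, dtype=float)
    areas = np.asarray(areas)
    groups = []
    for a in pd.unique(areas):
        g = np.log(tau[areas == a])
        if len(g) < 3:
            warnings.warn(f"area {a}: fewer than 3 neurons, excluded from area tests")
            continue
        groups.append(g)
    if len(groups) < 2:
        raise ValueError("need at least 2 areas with >= 3 neurons")
    if all(np.array_equal(g, groups[0]) for g in groups[1:]):
        # identical samples: no location or dispersion difference
        kw_stat, kw_p = 0.0, 1.0
        b_stat, b_p = 0.0, 1.0
    else:
        kw_stat, kw_p = stats.kruskal(*groups)
        b_stat, b_p = stats.bartlett(*groups)
    return {
        "bartlett_stat": float(b_stat),
        "bartlett_p": float(b_p),
        "kruskal_stat": float(kw_stat),
        "kruskal_p": float(kw_p),
    }


# ---------------------------------------------------------------------------
# sorted display matrix


def sorted_display_matrix(
    cpd_matrix: np.ndarray, tau: np.ndarray, kernel_sd: float = 2.0
) -> tuple[np.ndarray, np.ndarray]:
    """Rows sorted by ascending tau, then Gaussian-smoothed across neurons.

    Smoothing acts along the neuron axis only (SD in rows, truncated at
    ±4 SD, reflected at the edges — a boundary treatment under which a
    constant matrix is unchanged and the grand mean is conserved exactly).
    Returns (smoothed matrix, row order).
    """
    from scipy.ndimage import gaussian_filter1d

    cpd_matrix = np.asarray(cpd_matrix, dtype=float)
    order = np.argsort(np.asarray(tau, dtype=float), kind="stable")
    m = cpd_matrix[order]
    return gaussian_filter1d(m, sigma=kernel_sd, axis=0, mode="reflect", truncate=4.0), order
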