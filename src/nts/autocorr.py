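"""Spike-count autocorrelation and exponential timescale fitting.

The resting (fixation-period) raster of each neuron is binned into twenty
successive 50 ms bins, and the across-trial Pearson correlation between
every pair of bins forms a 20×20 autocorrelation matrix.  Collapsing the
matrix over lag gives the autocorrelation function R(k·delta), which is
fitted with a single exponential decay

    R(k·delta) = A * ( exp(-k·delta / tau) + B )

where ``tau`` is the neuron's intrinsic timescale, ``A`` the amplitude and
``B`` a dimensionless offset.  Because short lags are often depressed by
refractoriness or negative adaptation, the fit starts at the lag where the
largest drop between consecutive lags lands, and only later lags enter the
fit.

Neurons whose resting activity cannot support the fit are screened out by
objective criteria (low rate, no early decline, silent bins, degenerate
sign, poor goodness of fit); a sliding Kruskal–Wallis filter can restrict
analysis to the longest run of trials without significant rate drift.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import least_squares

from .io_core import SessionDataset, epoch_counts_all

EXCLUSION_REASONS = (
    "low_rate",
    "no_decline",
    "zero_bin",
    "sign_degenerate",
    "poor_fit",
    "none",
)


class InsufficientDataError(ValueError):
    pass


@dataclass
class ACFProfile:
    """Across-trial autocorrelation structure of one neuron's resting bins."""

    neuron_id: str
    bin_matrix: np.ndarray  # n_bins × n_bins Pearson r, NaN where undefined
    lag_acf: np.ndarray  # mean r at lag k, k = 1..n_bins-1
    n_trials_used: int
    fixation_rate: float  # spikes/s over the analysis window
    bin_width: float = 0.05
    bin_totals: np.ndarray | None = None  # spikes per bin summed over trials

    @property
    def lags(self) -> np.ndarray:
        """Lag values in seconds for ``lag_acf`` (k·delta, k = 1..n-1)."""
        return self.bin_width * np.arange(1, len(self.lag_acf) + 1)

    @property
    def nan_fraction(self) -> float:
        off = ~np.eye(len(self.bin_matrix), dtype=bool)
        return float(np.mean(~np.isfinite(self.bin_matrix[off])))


@dataclass
class ExponentialFit:
    tau: float  # s
    A: float
    B: float
    fit_start_lag: int  # index k of the first lag entering the fit
    sse: float
    r_squared: float
    included: bool = True
    exclusion_reason: str = "none"
    n_points: int = 0


@dataclass
class StationaritySelection:
    neuron_id: str
    first: int  # first selected trial index (inclusive)
    last: int  # last selected trial index (inclusive)
    fraction_removed: float
    all_selected: bool = False
    degenerate: bool = False

    @property
    def selected(self) -> np.ndarray:
        return np.arange(self.first, self.last + 1)


# ---------------------------------------------------------------------------
# ACF estimation


def acf_matrix(counts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Bin-pair Pearson correlation matrix and its lag collapse.

    ``counts`` is trials × bins.  Zero-variance columns give NaN rows and
    columns (flagged, excluded from lag means); the diagonal is 1 wherever
    the bin has variance.  ``lag_acf[k-1]`` is the unweighted mean of the
    (n_bins - k) matrix entries at lag k.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[0] < 3:
        raise InsufficientDataError("need >= 3 trials to correlate spike counts")
    n_bins = counts.shape[1]
    sd = counts.std(axis=0)
    ok = sd > 0
    mat = np.full((n_bins, n_bins), np.nan)
    if ok.sum() >= 1:
        sub = np.corrcoef(counts[:, ok], rowvar=False)
        if ok.sum() == 1:
            sub = np.array([[1.0]])
        idx = np.flatnonzero(ok)
        mat[np.ix_(idx, idx)] = sub
    lag_acf = np.full(n_bins - 1, np.nan)
    for k in range(1, n_bins):
        vals = np.diagonal(mat, offset=k)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            lag_acf[k - 1] = np.nanmean(vals)
    return mat, lag_acf


def compute_profile(
    counts: np.ndarray, neuron_id: str = "", bin_width: float = 0.05
) -> ACFProfile:
    """Full ACF profile (matrix, lag collapse, rate bookkeeping) from counts."""
    counts = np.asarray(counts)
    mat, lag_acf = acf_matrix(counts)
    window = counts.shape[1] * bin_width
    rate = counts.sum() / (counts.shape[0] * window) if counts.shape[0] else 0.0
    return ACFProfile(
        neuron_id=neuron_id,
        bin_matrix=mat,
        lag_acf=lag_acf,
        n_trials_used=counts.shape[0],
        fixation_rate=float(rate),
        bin_width=bin_width,
        bin_totals=counts.sum(axis=0),
    )


# ---------------------------------------------------------------------------
# exponential fit


def find_fit_start(lag_acf: np.ndarray, rule: str = "largest_drop") -> int:
    """Index (1-based lag index) of the first lag entering the fit.

    ``largest_drop``: locate the consecutive lag pair with the most negative
    difference; the fit begins at the lag the drop lands on.
    ``first_drop``: the first consecutive pair showing any reduction.
    Either way the pre-drop plateau (refractoriness / negative adaptation)
    is excluded.  ``none`` uses every lag (for curves already windowed).
    Lag indices are 1-based: index k means lag k·delta.
    """
    if rule == "none":
        return 1
    y = np.asarray(lag_acf, dtype=float)
    d = np.diff(y)  # d[i] = y[i+1] - y[i], drop between lag i+1 and i+2
    finite = np.isfinite(d)
    if not finite.any():
        return 1
    if rule == "largest_drop":
        i = int(np.nanargmin(np.where(finite, d, np.inf)))
        return i + 2  # lag index where the drop lands
    if rule == "first_drop":
        neg = np.flatnonzero(finite & (d < 0))
        return int(neg[0]) + 2 if len(neg) else 2
    raise ValueError(f"unknown start rule {rule!r}")


def _exp_model(theta: np.ndarray, lags: np.ndarray) -> np.ndarray:
    tau, a, b = theta
    return a * (np.exp(-lags / tau) + b)


def fit_exponential(
    lag_acf: np.ndarray,
    lags: np.ndarray | None = None,
    start_rule: str = "largest_drop",
    bin_width: float = 0.05,
    tau_bounds: tuple[float, float] = (1e-3, 10.0),
    b_bounds: tuple[float, float] = (0.0, 2.0),
    n_starts: int = 8,
    min_points: int = 4,
) -> ExponentialFit:
    """Bounded multi-start least-squares fit of the exponential decay.

    The objective is multimodal in (tau, A, B) on short windows, so the
    optimiser is restarted from ``n_starts`` tau values log-spaced across
    the bounds; the best residual sum of squares wins.  The offset B
    absorbs autocorrelation from timescales too slow to resolve inside the
    lag window and is therefore bounded below at zero by default — letting
    B go far negative lets a slow exponential mimic a fast decay above a
    spurious negative floor, which destabilises tau.  Too few usable
    points (or failure from every start) yields an excluded fit flagged
    ``poor_fit``.
    """
    y_all = np.asarray(lag_acf, dtype=float)
    if lags is None:
        lags = bin_width * np.arange(1, len(y_all) + 1)
    lags = np.asarray(lags, dtype=float)
    start = find_fit_start(y_all, start_rule)
    sel = np.arange(start - 1, len(y_all))
    sel = sel[np.isfinite(y_all[sel])]
    y = y_all[sel]
    x = lags[sel]

    failed = ExponentialFit(
        tau=np.nan, A=np.nan, B=np.nan, fit_start_lag=start, sse=np.inf,
        r_squared=0.0, included=False, exclusion_reason="poor_fit", n_points=len(y),
    )
    if len(y) < min_points:
        return failed

    a0 = y[0] - y[-1]
    if not np.isfinite(a0) or abs(a0) < 1e-12:
        a0 = 1e-3 if a0 >= 0 else -1e-3
    b0 = float(np.clip(y[-1] / a0, b_bounds[0] + 1e-6, b_bounds[1] - 1e-6))
    lo = np.array([tau_bounds[0], -10.0, b_bounds[0]])
    hi = np.array([tau_bounds[1], 10.0, b_bounds[1]])
    best = None
    for tau0 in np.geomspace(max(2e-2, tau_bounds[0]), min(2.0, tau_bounds[1]), n_starts):
        theta0 = np.clip(np.array([tau0, a0, b0]), lo + 1e-12, hi - 1e-12)
        try:
            res = least_squares(
                lambda th: _exp_model(th, x) - y, theta0, bounds=(lo, hi),
                method="trf", max_nfev=200,
            )
        except Exception:
            continue
        sse = float(np.sum(res.fun**2))
        if best is None or sse < best[0]:
            best = (sse, res.x)
    if best is None:
        return failed
    sse, theta = best
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - sse / tss if tss > 0 else 0.0
    return ExponentialFit(
        tau=float(theta[0]), A=float(theta[1]), B=float(theta[2]),
        fit_start_lag=start, sse=sse, r_squared=float(r2), n_points=len(y),
    )


# ---------------------------------------------------------------------------
# inclusion screen


def objective_inclusion(
    profile: ACFProfile,
    ls_fit: ExponentialFit,
    min_rate: float = 1.0,
    max_drop_lag: int = 5,
    r2_threshold: float = 0.2,
    sign_rule: str = "default",
    max_nan_fraction: float = 0.25,
) -> tuple[bool, str]:
    """Objective screen for neurons whose resting ACF supports the fit.

    Criteria, in order (the first failure is recorded):

    * ``low_rate`` — fixation rate must exceed ``min_rate`` (1 Hz);
    * ``no_decline`` — the largest consecutive-lag drop must land within
      the first 250 ms of lags (index <= ``max_drop_lag``);
    * ``zero_bin`` — no bin may be silent across all trials (also covers
      profiles whose correlation matrix is mostly undefined);
    * ``sign_degenerate`` — ``default``: amplitude A must be positive
      (a negative or zero A means no decaying component); ``strict``:
      exclude when A and B are both positive;
    * ``poor_fit`` — goodness of fit r² must reach ``r2_threshold``
      (automated surrogate for manual curation of non-exponential ACFs).
    """
    if profile.fixation_rate <= min_rate:
        return False, "low_rate"
    d = np.diff(np.asarray(profile.lag_acf, dtype=float))
    has_drop = np.any(np.isfinite(d) & (d < 0))
    if not has_drop or find_fit_start(profile.lag_acf, "largest_drop") > max_drop_lag:
        return False, "no_decline"
    if profile.bin_totals is not None and np.any(profile.bin_totals == 0):
        return False, "zero_bin"
    if profile.nan_fraction > max_nan_fraction:
        return False, "zero_bin"
    if np.isfinite(ls_fit.A):
        if sign_rule == "default" and ls_fit.A <= 0:
            return False, "sign_degenerate"
        if sign_rule == "strict" and ls_fit.A > 0 and ls_fit.B > 0:
            return False, "sign_degenerate"
    if not np.isfinite(ls_fit.tau) or ls_fit.r_squared < r2_threshold:
        return False, "poor_fit"
    return True, "none"


# ---------------------------------------------------------------------------
# trial-stationarity filter


def _kw_pvalue(groups: list[np.ndarray]) -> float:
    flat = np.concatenate(groups)
    if np.all(flat == flat[0]):
        return 1.0  # no variance anywhere: no evidence of difference
    try:
        return float(stats.kruskal(*groups).pvalue)
    except ValueError:
        return 1.0


def stationarity_filter(
    trial_counts: np.ndarray,
    neuron_id: str = "",
    window: int = 100,
    n_groups: int = 4,
    alpha: float = 0.005,
) -> StationaritySelection:
    """Longest run of trials whose resting rate shows no significant drift.

    A 100-trial window slides across the session; within each window the
    counts are split into four successive groups of 25 and compared with a
    Kruskal–Wallis test.  A window passes when p > ``alpha``.  Maximal runs
    of consecutive passing windows are merged — a run of window starts
    [s0, s1] covers trials [s0, s1 + window - 1] — and the selection is the
    longest covered trial interval, so every trial selected sits inside a
    passing window and no failing window interrupts the run (a rate step
    mid-session therefore confines the selection to one side of the step).
    """
    x = np.asarray(trial_counts, dtype=float)
    n = len(x)
    if n < window:
        return StationaritySelection(neuron_id, 0, n - 1, 0.0, all_selected=True)
    group_size = window // n_groups
    pvals = np.empty(n - window + 1)
    for s in range(n - window + 1):
        w = x[s : s + window]
        groups = [w[g * group_size : (g + 1) * group_size] for g in range(n_groups)]
        pvals[s] = _kw_pvalue(groups)
    passing = pvals > alpha
    if not passing.any():
        s = int(np.argmax(pvals))  # all windows fail: fall back to best one
        warnings.warn(
            f"{neuron_id or 'neuron'}: no stationary 100-trial window; "
            "falling back to the least non-stationary window"
        )
        return StationaritySelection(
            neuron_id, s, s + window - 1, 1.0 - window / n, degenerate=True
        )
    # longest run of consecutive passing windows -> covered trial interval
    best_len = best_start = 0
    cur_len = cur_start = 0
    for i, ok in enumerate(passing):
        if ok:
            if cur_len == 0:
                cur_start = i
            cur_len += 1
            if cur_len > best_len:
                best_len, best_start = cur_len, cur_start
        else:
            cur_len = 0
    first = best_start
    last = best_start + best_len - 1 + window - 1
    n_sel = last - first + 1
    return StationaritySelection(
        neuron_id, first, last, 1.0 - n_sel / n, all_selected=n_sel == n
    )


# ---------------------------------------------------------------------------
# population-level fit and cohort driver


def population_fit(
    profiles: dict[str, ACFProfile],
    area_of: dict[str, str],
    start_rule: str = "largest_drop",
) -> dict[str, ExponentialFit]:
    """Average lag ACFs within each area, then fit the exponential once.

    ``area_of`` maps neuron_id to area label.  Areas with fewer than two
    usable profiles are skipped with a warning.
    """
    by_area: dict[str, list[np.ndarray]] = {}
    bin_width = 0.05
    for nid, prof in profiles.items():
        by_area.setdefault(area_of[nid], []).append(prof.lag_acf)
        bin_width = prof.bin_width
    fits = {}
    for area, curves in by_area.items():
        stack = np.vstack(curves)
        usable = ~np.all(~np.isfinite(stack), axis=1)
        if usable.sum() == 0:
            warnings.warn(f"area {area}: no usable profiles; skipped")
            continue
        if len(curves) < 2:
            warnings.warn(f"area {area}: fewer than 2 profiles; fit is single-neuron")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mean_curve = np.nanmean(stack, axis=0)
        fits[area] = fit_exponential(
            mean_curve, start_rule=start_rule, bin_width=bin_width
        )
    return fits


def analyze_cohort(
    ds: SessionDataset,
    event: str = "fixation_on",
    window: tuple[float, float] | None = None,
    bin_width: float = 0.05,
    filter_drift: bool = False,
    start_rule: str = "largest_drop",
    min_rate: float = 1.0,
    r2_threshold: float = 0.2,
    sign_rule: str = "default",
) -> tuple[pd.DataFrame, dict[str, ACFProfile]]:
    """Per-neuron ACF profile + exponential fit + inclusion screen.

    Returns a table with one row per neuron (tau, A, B, fit_start_lag,
    r_squared, included, exclusion_reason, n_trials_used, fixation_rate,
    fraction_removed) and the dict of ACF profiles.
    """
    counts_all = epoch_counts_all(ds, event, window, bin_width)
    area_of = dict(zip(ds.neurons["neuron_id"], ds.neurons["area"]))
    rows = []
    profiles: dict[str, ACFProfile] = {}
    for nid, counts in counts_all.items():
        frac_removed = 0.0
        if filter_drift:
            sel = stationarity_filter(counts.sum(axis=1), neuron_id=nid)
            counts = counts[sel.selected]
            frac_removed = sel.fraction_removed
        try:
            prof = compute_profile(counts, neuron_id=nid, bin_width=bin_width)
        except InsufficientDataError:
            continue
        profiles[nid] = prof
        fit = fit_exponential(prof.lag_acf, lags=prof.lags, start_rule=start_rule)
        included, reason = objective_inclusion(
            prof, fit, min_rate=min_rate, r2_threshold=r2_threshold, sign_rule=sign_rule
        )
        rows.append(
            {
                "neuron_id": nid,
                "area": area_of.get(nid),
                "tau": fit.tau,
                "A": fit.A,
                "B": fit.B,
                "fit_start_lag": fit.fit_start_lag,
                "sse": fit.sse,
                "r_squared": fit.r_squared,
                "included": included,
                "exclusion_reason": reason,
                "n_trials_used": prof.n_trials_used,
                "fixation_rate": prof.fixation_rate,
                "fraction_removed": frac_removed,
            }
        )
    return pd.DataFrame(rows), profiles
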