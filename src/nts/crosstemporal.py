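"""Split-half cross-temporal population pattern analysis.

The chosen-value regression coefficient (Z-score) of every neuron is
computed separately on odd and even trials, giving two neuron × time
coefficient arrays per epoch.  The population vector at time t1 of one
half is Pearson-correlated (across neurons) with the vector at t2 of the
other half; averaging the odd→even and even→odd projections gives the
cross-temporal matrix.  Splitting by trial parity keeps the two halves
statistically independent, so shared trial-by-trial noise cannot inflate
the correlations.

Off-diagonal structure of the matrix distinguishes population-coding
regimes: *transient* codes correlate only near the diagonal, *sustained*
codes extend far off the diagonal (and across epochs), and *reactivation*
codes link two separated windows without the bridge between them.

Significance is assessed with 2-D cluster-based permutation tests: pixels
with uncorrected p < 0.01 are thresholded, connected components (4- or
8-adjacency) form clusters scored by pixel count, and the null shuffles
neuron identity in the even half (breaking cross-half pattern alignment
while preserving each half's marginal structure) — a time-shuffle mode is
available as an alternative.  Two groups' matrices are compared pixelwise
with Fisher's r-to-Z transform, with a group-label-shuffle null.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats


@dataclass
class SplitHalfZ:
    """Odd/even-half coefficient arrays: {event: neurons × bins Z}."""

    neuron_ids: list[str]
    odd: dict[str, np.ndarray]
    even: dict[str, np.ndarray]
    times: dict[str, np.ndarray]
    n_trials: tuple[int, int]  # (odd, even)


@dataclass
class Cluster2D:
    pixels: np.ndarray  # boolean mask on the matrix grid
    area: int
    corrected_p: float

    @property
    def significant_05(self) -> bool:
        return self.corrected_p < 0.05


@dataclass
class CrossTemporalMatrix:
    epoch_pair: tuple[str, str]  # row epoch, column epoch (event, slice label)
    matrix: np.ndarray  # t1 × t2 symmetrised correlation
    n_neurons: int
    # neuron-resolved blocks kept so permutation nulls can rebuild the matrix
    odd_1: np.ndarray = field(repr=False, default=None)
    even_1: np.ndarray = field(repr=False, default=None)
    odd_2: np.ndarray = field(repr=False, default=None)
    even_2: np.ndarray = field(repr=False, default=None)
    clusters: list[Cluster2D] = field(default_factory=list)


# ---------------------------------------------------------------------------
# split-half coefficients


def split_half_coefficients(
    ds,
    events: dict[str, tuple[float, float]] | None = None,
    regressors: tuple[str, ...] = ("chosen_value",),
    regressor: str = "chosen_value",
    bin_ms: float = 10.0,
    kernel_ms: float = 100.0,
    neuron_ids: list[str] | None = None,
) -> SplitHalfZ:
    """Per-half, per-neuron binwise regression Z for the regressor of interest.

    Trial halves are defined by the parity of ``trial_index_in_session``.
    """
    from .cpd import binned_rates_all, binwise_regression, build_design

    if events is None:
        events = {"choice_on": ds.epochs["choice_on"], "reward_on": ds.epochs["reward_on"]}
    trials = ds.completed_trials()
    parity = trials["trial_index_in_session"].to_numpy() % 2
    halves = {"odd": np.flatnonzero(parity == 1), "even": np.flatnonzero(parity == 0)}
    for name, idx in halves.items():
        if len(idx) < 4:
            raise ValueError(f"{name} half has fewer than 4 trials")

    ids = neuron_ids
    out = {"odd": {}, "even": {}}
    times = {}
    for event, window in events.items():
        rates, t = binned_rates_all(ds, event, window, bin_ms, kernel_ms)
        times[event] = t
        if ids is None:
            ids = list(rates)
        for half, idx in halves.items():
            sub_trials = trials.iloc[idx]
            design = build_design(sub_trials, regressors)
            z = np.empty((len(ids), len(t)))
            for i, nid in enumerate(ids):
                series = binwise_regression(rates[nid][idx], design, t, nid, event)
                z[i] = series.for_regressor(regressor)[1]
            out[half][event] = z
    return SplitHalfZ(
        neuron_ids=list(ids),
        odd=out["odd"],
        even=out["even"],
        times=times,
        n_trials=(len(halves["odd"]), len(halves["even"])),
    )


# ---------------------------------------------------------------------------
# cross-correlation matrices


def _standardize(z: np.ndarray) -> np.ndarray:
    """Z-score each column across neurons (for fast Pearson via matmul)."""
    m = z - z.mean(axis=0, keepdims=True)
    sd = m.std(axis=0, keepdims=True)
    sd[sd == 0] = np.inf
    return m / sd


def _corr_block(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson r across neurons between columns of a (t1) and b (t2)."""
    n = a.shape[0]
    return _standardize(a).T @ _standardize(b) / n


def symmetrize(m_oe: np.ndarray, m_eo: np.ndarray) -> np.ndarray:
    """Average the odd→even and even→odd projections."""
    return 0.5 * (m_oe + m_eo)


def cross_correlate(
    split: SplitHalfZ,
    epoch_1: str,
    epoch_2: str,
    slice_1: slice | None = None,
    slice_2: slice | None = None,
    label_1: str | None = None,
    label_2: str | None = None,
) -> CrossTemporalMatrix:
    """Cross-temporal correlation matrix for one epoch pair.

    ``slice_1`` / ``slice_2`` cut sub-windows (in bins) out of each epoch's
    grid — e.g. the pre-reward second of a reward-aligned epoch.  Entry
    (t1, t2) is the across-neuron correlation between the epoch-1 vector at
    t1 of one half and the epoch-2 vector at t2 of the other, averaged over
    both half assignments.
    """
    if len(split.neuron_ids) < 5:
        raise ValueError("cross-neuron correlation needs >= 5 neurons")
    s1 = slice_1 or slice(None)
    s2 = slice_2 or slice(None)
    o1, e1 = split.odd[epoch_1][:, s1], split.even[epoch_1][:, s1]
    o2, e2 = split.odd[epoch_2][:, s2], split.even[epoch_2][:, s2]
    mat = symmetrize(_corr_block(o1, e2), _corr_block(e1, o2))
    return CrossTemporalMatrix(
        epoch_pair=(label_1 or epoch_1, label_2 or epoch_2),
        matrix=mat,
        n_neurons=len(split.neuron_ids),
        odd_1=o1, even_1=e1, odd_2=o2, even_2=e2,
    )


# ---------------------------------------------------------------------------
# 2-D cluster permutation test


def _r_threshold(n: int, alpha: float) -> float:
    """|r| above which the correlation test at n samples has p < alpha."""
    t_crit = stats.t.ppf(1.0 - alpha / 2.0, n - 2)
    return float(t_crit / np.sqrt(n - 2 + t_crit**2))


def _clusters_from_mask(mask: np.ndarray, adjacency: int) -> list[np.ndarray]:
    structure = (
        np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
        if adjacency == 4
        else np.ones((3, 3))
    )
    labels, n = ndimage.label(mask, structure=structure)
    return [labels == i for i in range(1, n + 1)]


def _max_cluster_area(mask: np.ndarray, adjacency: int) -> int:
    clusters = _clusters_from_mask(mask, adjacency)
    return max((int(c.sum()) for c in clusters), default=0)


def cluster_test_2d(
    ctm: CrossTemporalMatrix,
    alpha_form: float = 0.01,
    n_perm: int = 10000,
    adjacency: int = 4,
    seed: int = 0,
    null_mode: str = "neuron",
) -> CrossTemporalMatrix:
    """Annotate a cross-temporal matrix with permutation-corrected clusters.

    Pixels whose correlation is individually significant at ``alpha_form``
    (two-sided test at ``n_neurons``) are thresholded; connected
    components are scored by area.  The null rebuilds the matrix with
    neuron identity permuted in the even half only (``null_mode='time'``
    instead shuffles the even half's time bins), recording the maximal
    cluster area per permutation; corrected p = (r + 1) / (n_perm + 1).
    """
    rng = np.random.default_rng(seed)
    n = ctm.n_neurons
    r_crit = _r_threshold(n, alpha_form)
    obs_clusters = _clusters_from_mask(np.abs(ctm.matrix) > r_crit, adjacency)

    zo1, ze1 = _standardize(ctm.odd_1), _standardize(ctm.even_1)
    zo2, ze2 = _standardize(ctm.odd_2), _standardize(ctm.even_2)
    null_areas = np.empty(n_perm)
    for i in range(n_perm):
        if null_mode == "neuron":
            perm = rng.permutation(n)
            pe1, pe2 = ze1[perm], ze2[perm]
            m = 0.5 * (zo1.T @ pe2 + pe1.T @ zo2) / n
        elif null_mode == "time":
            p1 = rng.permutation(ze1.shape[1])
            p2 = rng.permutation(ze2.shape[1])
            m = 0.5 * (zo1.T @ ze2[:, p2] + ze1[:, p1].T @ zo2) / n
        else:
            raise ValueError(f"unknown null_mode {null_mode!r}")
        null_areas[i] = _max_cluster_area(np.abs(m) > r_crit, adjacency)

    clusters = []
    for cmask in obs_clusters:
        area = int(cmask.sum())
        r = int(np.sum(null_areas >= area))
        clusters.append(Cluster2D(pixels=cmask, area=area, corrected_p=(r + 1) / (n_perm + 1)))
    ctm.clusters = sorted(clusters, key=lambda c: -c.area)
    return ctm


# ---------------------------------------------------------------------------
# group comparison (Fisher r-to-Z)


def fisher_z_diff(ra: np.ndarray, rb: np.ndarray, na: int, nb: int) -> np.ndarray:
    """Pixelwise z statistic for the difference of two correlation matrices."""
    clip = 0.999999
    za = np.arctanh(np.clip(ra, -clip, clip))
    zb = np.arctanh(np.clip(rb, -clip, clip))
    return (za - zb) / np.sqrt(1.0 / (na - 3) + 1.0 / (nb - 3))


def compare_groups(
    ctm_a: CrossTemporalMatrix,
    ctm_b: CrossTemporalMatrix,
    alpha_form: float = 0.01,
    n_perm: int = 10000,
    adjacency: int = 4,
    seed: int = 0,
) -> tuple[int, float, np.ndarray]:
    """Largest difference cluster between two groups' matrices.

    Pixels where Fisher's r-to-Z two-sample statistic has p < ``alpha_form``
    form difference clusters; the null shuffles the assignment of neurons
    to the two groups and recomputes both matrices each time.  Returns
    (largest observed cluster area, corrected p, observed difference mask).
    """
    na, nb = ctm_a.n_neurons, ctm_b.n_neurons
    if na < 5 or nb < 5:
        raise ValueError("each group needs >= 5 neurons")
    if ctm_a.matrix.shape != ctm_b.matrix.shape:
        raise ValueError("groups must share the epoch-pair grid")
    z_crit = stats.norm.ppf(1.0 - alpha_form / 2.0)
    obs_mask = np.abs(fisher_z_diff(ctm_a.matrix, ctm_b.matrix, na, nb)) > z_crit
    obs_area = _max_cluster_area(obs_mask, adjacency)

    # pooled neuron blocks for label shuffling
    blocks = [
        np.vstack([getattr(ctm_a, name), getattr(ctm_b, name)])
        for name in ("odd_1", "even_1", "odd_2", "even_2")
    ]
    n = na + nb
    rng = np.random.default_rng(seed)
    null_areas = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(n)
        ia, ib = perm[:na], perm[na:]
        mats = []
        for idx, count in ((ia, na), (ib, nb)):
            o1, e1, o2, e2 = (blk[idx] for blk in blocks)
            mats.append(0.5 * (_corr_block(o1, e2) + _corr_block(e1, o2)))
        mask = np.abs(fisher_z_diff(mats[0], mats[1], na, nb)) > z_crit
        null_areas[i] = _max_cluster_area(mask, adjacency)
    r = int(np.sum(null_areas >= obs_area)) if obs_area else n_perm
    corrected_p = (r + 1) / (n_perm + 1)
    return obs_area, float(corrected_p), obs_mask
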