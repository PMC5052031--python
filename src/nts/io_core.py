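"""Canonical data model for trial-aligned spike data.

A :class:`SessionDataset` bundles three tables:

* a **spike table** — one row per spike, with times in seconds relative to a
  named alignment event (``fixation_on``, ``choice_on``, ``reward_on``);
* a **trial table** — one row per trial with the behavioural design
  (chosen value, its benefit and cost components, optional nuisance
  regressors, and a ``completed`` flag);
* **neuron metadata** — one row per neuron with its cortical area
  (DLPFC, OFC or ACC) and session.

The on-disk representation is plain CSV with fixed headers (see
:func:`read_dataset` / :func:`write_dataset`), chosen as the simplest
faithful carrier; rich electrophysiology containers (NWB, neo) are out of
scope.  Binned spike counts for downstream analyses come from
:func:`epoch_counts`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

EVENTS = ("fixation_on", "choice_on", "reward_on")
AREAS = ("DLPFC", "OFC", "ACC")

#: Default alignment windows, seconds relative to each event.  The fixation
#: epoch is the canonical 1 s "resting" period; the reward epoch spans the
#: second before and after reward onset so that pre- and post-outcome
#: analyses share one alignment.
DEFAULT_EPOCHS: Mapping[str, tuple[float, float]] = {
    "fixation_on": (0.0, 1.0),
    "choice_on": (0.0, 1.0),
    "reward_on": (-1.0, 1.0),
}

SPIKE_COLUMNS = ["neuron_id", "trial_id", "event", "spike_time"]
TRIAL_COLUMNS = [
    "session_id",
    "trial_id",
    "trial_index_in_session",
    "completed",
    "chosen_value",
    "chosen_benefit",
    "chosen_cost",
]
NEURON_COLUMNS = ["neuron_id", "session_id", "area"]


class SchemaError(ValueError):
    """A table is missing a required column."""


class IntegrityError(ValueError):
    """Cross-table referential integrity is violated."""


@dataclass
class SessionDataset:
    """Trial-aligned spikes + design table + neuron metadata.

    ``trials`` may contain extra (nuisance) columns beyond the required
    ones; they are carried through unchanged and can be referenced by name
    when building design matrices.
    """

    spikes: pd.DataFrame
    trials: pd.DataFrame
    neurons: pd.DataFrame
    epochs: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_EPOCHS)
    )

    def __post_init__(self) -> None:
        validate_dataset(self)

    # -- convenience accessors -------------------------------------------
    @property
    def neuron_ids(self) -> list[str]:
        return list(self.neurons["neuron_id"])

    def completed_trials(self) -> pd.DataFrame:
        """Trial rows with ``completed == True``, in session order."""
        out = self.trials[self.trials["completed"].astype(bool)]
        return out.sort_values(["session_id", "trial_index_in_session"])

    def nuisance_columns(self) -> list[str]:
        return [c for c in self.trials.columns if c not in TRIAL_COLUMNS]

    def spikes_for(self, neuron_id: str, event: str) -> pd.DataFrame:
        m = (self.spikes["neuron_id"] == neuron_id) & (self.spikes["event"] == event)
        return self.spikes[m]

    def subset_neurons(self, neuron_ids) -> "SessionDataset":
        keep = set(neuron_ids)
        return replace(
            self,
            spikes=self.spikes[self.spikes["neuron_id"].isin(keep)].reset_index(drop=True),
            neurons=self.neurons[self.neurons["neuron_id"].isin(keep)].reset_index(drop=True),
        )


def _require_columns(df: pd.DataFrame, required: list[str], name: str) -> None:
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{name} is missing required column {col!r}")


def validate_dataset(ds: SessionDataset) -> None:
    _require_columns(ds.spikes, SPIKE_COLUMNS, "spike table")
    _require_columns(ds.trials, TRIAL_COLUMNS, "trial table")
    _require_columns(ds.neurons, NEURON_COLUMNS, "neuron table")

    for event, (start, end) in ds.epochs.items():
        if not end > start:
            raise ValueError(f"epoch window for {event!r} is empty: [{start}, {end}]")

    if len(ds.trials) and ds.trials["trial_id"].duplicated().any():
        dups = ds.trials.loc[ds.trials["trial_id"].duplicated(), "trial_id"].tolist()
        raise IntegrityError(f"duplicate trial_id values: {sorted(set(dups))}")

    if len(ds.spikes):
        if not np.isfinite(ds.spikes["spike_time"].to_numpy(dtype=float)).all():
            raise IntegrityError("spike_time contains non-finite values")
        bad_event = set(ds.spikes["event"]) - set(EVENTS)
        if bad_event:
            raise SchemaError(f"unknown alignment events: {sorted(bad_event)}")
        known_trials = set(ds.trials["trial_id"])
        dangling = set(ds.spikes["trial_id"]) - known_trials
        if dangling:
            raise IntegrityError(
                "spike rows reference unknown trial_id values: "
                + ", ".join(str(t) for t in sorted(dangling))
            )
        known_neurons = set(ds.neurons["neuron_id"])
        orphan = set(ds.spikes["neuron_id"]) - known_neurons
        if orphan:
            raise IntegrityError(
                f"spike rows reference unknown neuron_id values: {sorted(orphan)}"
            )

    if len(ds.neurons):
        bad_area = set(ds.neurons["area"]) - set(AREAS)
        if bad_area:
            raise IntegrityError(f"unknown area labels: {sorted(bad_area)}")


def _canonicalize(ds: SessionDataset) -> SessionDataset:
    spikes = ds.spikes.sort_values(
        ["neuron_id", "trial_id", "event", "spike_time"], kind="mergesort"
    ).reset_index(drop=True)
    trials = ds.trials.sort_values(
        ["session_id", "trial_index_in_session"], kind="mergesort"
    ).reset_index(drop=True)
    neurons = ds.neurons.sort_values(["neuron_id"], kind="mergesort").reset_index(drop=True)
    return replace(ds, spikes=spikes, trials=trials, neurons=neurons)


def read_dataset(
    spike_path, trial_path, meta_path, epochs: Mapping[str, tuple[float, float]] | None = None
) -> SessionDataset:
    """Read a dataset from its three CSV files and validate it.

    Incomplete trials are retained (flagged by ``completed``); each analysis
    stage filters on the flag itself.
    """
    # round_trip parsing keeps write -> read -> write byte-stable
    spikes = pd.read_csv(spike_path, float_precision="round_trip")
    trials = pd.read_csv(trial_path, float_precision="round_trip")
    neurons = pd.read_csv(meta_path, float_precision="round_trip")
    if spikes.empty:
        spikes = spikes.reindex(columns=spikes.columns if len(spikes.columns) else SPIKE_COLUMNS)
    if "completed" in trials.columns:
        trials["completed"] = trials["completed"].astype(bool)
    ds = SessionDataset(
        spikes=spikes,
        trials=trials,
        neurons=neurons,
        epochs=dict(epochs or DEFAULT_EPOCHS),
    )
    return _canonicalize(ds)


def write_dataset(ds: SessionDataset, out_dir) -> tuple[Path, Path, Path]:
    """Write ``spikes.csv``, ``trials.csv`` and ``neurons.csv`` under *out_dir*.

    Tables are canonically sorted and floats written with ``repr``
    round-tripping, so write→read→write is byte-stable.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ds = _canonicalize(ds)
    paths = (out / "spikes.csv", out / "trials.csv", out / "neurons.csv")
    ds.spikes.to_csv(paths[0], index=False)
    ds.trials.to_csv(paths[1], index=False)
    ds.neurons.to_csv(paths[2], index=False)
    return paths


def epoch_counts(
    ds: SessionDataset,
    neuron_id: str,
    event: str,
    window: tuple[float, float] | None = None,
    bin_width: float = 0.05,
) -> np.ndarray:
    """Bin one neuron's spikes into a completed-trials × bins count matrix.

    Bins are half-open ``[left, right)``: a spike exactly at the window end
    is excluded.  Trials are ordered by ``trial_index_in_session``.
    """
    if window is None:
        window = ds.epochs[event]
    start, end = window
    n_bins_f = (end - start) / bin_width
    n_bins = int(round(n_bins_f))
    if abs(n_bins_f - n_bins) > 1e-9 or n_bins <= 0:
        raise ValueError(
            f"window length {end - start} is not an integer multiple of bin_width {bin_width}"
        )
    trials = ds.completed_trials()
    trial_ids = trials["trial_id"].to_numpy()
    counts = np.zeros((len(trial_ids), n_bins), dtype=np.int64)
    sp = ds.spikes_for(neuron_id, event)
    if len(sp) == 0:
        return counts
    t = sp["spike_time"].to_numpy(dtype=float)
    in_win = (t >= start) & (t < end)
    if not in_win.any():
        return counts
    bins = np.floor((t[in_win] - start) / bin_width).astype(np.int64)
    bins = np.minimum(bins, n_bins - 1)  # guard float round at inner edges
    rows = pd.Series(np.arange(len(trial_ids)), index=trial_ids)
    tid = sp["trial_id"].to_numpy()[in_win]
    keep = np.isin(tid, trial_ids)
    idx = rows.loc[tid[keep]].to_numpy()
    np.add.at(counts, (idx, bins[keep]), 1)
    return counts


def epoch_counts_all(
    ds: SessionDataset,
    event: str,
    window: tuple[float, float] | None = None,
    bin_width: float = 0.05,
) -> dict[str, np.ndarray]:
    """Vectorized :func:`epoch_counts` for every neuron at once.

    Returns ``{neuron_id: completed-trials × bins count matrix}``; neurons
    with no spikes in the window get all-zero matrices.  Much faster than
    looping :func:`epoch_counts` over a large cohort because the spike
    table is scanned once.
    """
    if window is None:
        window = ds.epochs[event]
    start, end = window
    n_bins_f = (end - start) / bin_width
    n_bins = int(round(n_bins_f))
    if abs(n_bins_f - n_bins) > 1e-9 or n_bins <= 0:
        raise ValueError(
            f"window length {end - start} is not an integer multiple of bin_width {bin_width}"
        )
    trials = ds.completed_trials()
    trial_ids = trials["trial_id"].to_numpy()
    n_trials = len(trial_ids)
    neuron_ids = ds.neuron_ids
    out = {nid: np.zeros((n_trials, n_bins), dtype=np.int64) for nid in neuron_ids}
    if len(ds.spikes) == 0 or n_trials == 0:
        return out

    sp = ds.spikes
    m = sp["event"].to_numpy() == event
    t = sp["spike_time"].to_numpy(dtype=float)
    m &= (t >= start) & (t < end)
    if not m.any():
        return out
    t = t[m]
    bins = np.minimum(np.floor((t - start) / bin_width).astype(np.int64), n_bins - 1)
    rows = pd.Index(trial_ids).get_indexer(sp["trial_id"].to_numpy()[m])
    keep = rows >= 0
    ncodes, nuniq = pd.factorize(sp["neuron_id"].to_numpy()[m][keep])
    flat = rows[keep] * n_bins + bins[keep]
    # per-neuron histogram via one stable sort, avoiding a dense
    # neurons × trials × bins allocation
    order = np.argsort(ncodes, kind="stable")
    flat_sorted = flat[order]
    bounds = np.searchsorted(ncodes[order], np.arange(len(nuniq) + 1))
    for i, nid in enumerate(nuniq):
        if nid in out:
            seg = flat_sorted[bounds[i] : bounds[i + 1]]
            out[nid] = np.bincount(seg, minlength=n_trials * n_bins).reshape(
                n_trials, n_bins
            )
    return out
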