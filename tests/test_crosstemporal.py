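import numpy as np
import pytest

from nts.cpd import binwise_regression, build_design
from nts.crosstemporal import (
    CrossTemporalMatrix,
    SplitHalfZ,
    _clusters_from_mask,
    cluster_test_2d,
    compare_groups,
    cross_correlate,
    split_half_coefficients,
    symmetrize,
)


def _ctm_from_z(z_odd, z_even):
    split = SplitHalfZ(
        neuron_ids=[f"n{i}" for i in range(z_odd.shape[0])],
        odd={"e": z_odd},
        even={"e": z_even},
        times={"e": np.arange(z_odd.shape[1], dtype=float)},
        n_trials=(10, 10),
    )
    return cross_correlate(split, "e", "e")


# ---------------------------------------------------------------------------
# split-half coefficients


def test_halves_partition_the_trials(small_coding_dataset):
    _, ds, _ = small_coding_dataset
    split = split_half_coefficients(ds, neuron_ids=ds.neuron_ids[:5])
    assert sum(split.n_trials) == len(ds.completed_trials())
    assert split.odd["choice_on"].shape == (5, 100)


def test_too_few_trials_per_half_rejected(small_coding_dataset):
    _, ds, _ = small_coding_dataset
    ds_small = type(ds)(
        spikes=ds.spikes[ds.spikes["trial_id"] < 5].reset_index(drop=True),
        trials=ds.trials[ds.trials["trial_id"] < 5].reset_index(drop=True),
        neurons=ds.neurons,
        epochs=ds.epochs,
    )
    with pytest.raises(ValueError, match="fewer than 4"):
        split_half_coefficients(ds_small)


def test_deterministic_rates_give_identical_half_patterns():
    """With noise-free value-locked rates, odd and even Z agree exactly."""
    import pandas as pd

    rng = np.random.default_rng(0)
    n = 40
    v = rng.normal(size=n)
    trials = pd.DataFrame(
        {
            "session_id": "S1",
            "trial_id": np.arange(n),
            "trial_index_in_session": np.arange(n),
            "completed": True,
            "chosen_value": v,
            "chosen_benefit": v,
            "chosen_cost": 0.0,
        }
    )
    rates = 2.0 * v[:, None] + 5.0 + np.zeros((n, 12))
    odd, even = np.arange(n) % 2 == 1, np.arange(n) % 2 == 0
    t = np.arange(12) * 0.01
    s_odd = binwise_regression(rates[odd], build_design(trials[odd]), t)
    s_even = binwise_regression(rates[even], build_design(trials[even]), t)
    c_odd, z_odd, _ = s_odd.for_regressor("chosen_value")
    c_even, z_even, _ = s_even.for_regressor("chosen_value")
    # a noise-free linear code saturates CPD in both halves and gives the
    # same (positive) coefficient pattern; |Z| is limited only by round-off
    np.testing.assert_allclose(c_odd, 1.0, atol=1e-9)
    np.testing.assert_allclose(c_even, 1.0, atol=1e-9)
    assert (z_odd > 1e3).all() and (z_even > 1e3).all()


# ---------------------------------------------------------------------------
# cross-correlation matrices


def test_identical_population_patterns_correlate_perfectly():
    rng = np.random.default_rng(1)
    pattern = rng.normal(size=8)
    z = np.tile(pattern[:, None], (1, 3))
    ctm = _ctm_from_z(z, z.copy())
    np.testing.assert_allclose(ctm.matrix, 1.0, atol=1e-12)


def test_symmetrize_is_idempotent():
    rng = np.random.default_rng(2)
    m1, m2 = rng.random((6, 6)), rng.random((6, 6))
    s = symmetrize(m1, m2)
    np.testing.assert_allclose(symmetrize(s, s), s)


def test_matrix_entries_bounded():
    rng = np.random.default_rng(3)
    ctm = _ctm_from_z(rng.normal(size=(10, 7)), rng.normal(size=(10, 7)))
    assert (np.abs(ctm.matrix) <= 1.0 + 1e-12).all()


def test_too_few_neurons_rejected():
    rng = np.random.default_rng(4)
    with pytest.raises(ValueError, match="5 neurons"):
        _ctm_from_z(rng.normal(size=(3, 5)), rng.normal(size=(3, 5)))


# ---------------------------------------------------------------------------
# 2-D cluster finding vs a brute-force flood fill


def _flood_fill_areas(mask, adjacency):
    """Independent oracle: BFS connected components on a boolean grid."""
    mask = mask.copy()
    if adjacency == 4:
        steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        steps = [(i, j) for i in (-1, 0, 1) for j in (-1, 0, 1) if (i, j) != (0, 0)]
    seen = np.zeros_like(mask, dtype=bool)
    areas = []
    for i in range(mask.shape[0]):
        for j in range(mask.shape[1]):
            if mask[i, j] and not seen[i, j]:
                stack, size = [(i, j)], 0
                seen[i, j] = True
                while stack:
                    a, b = stack.pop()
                    size += 1
                    for da, db in steps:
                        x, y = a + da, b + db
                        if (
                            0 <= x < mask.shape[0]
                            and 0 <= y < mask.shape[1]
                            and mask[x, y]
                            and not seen[x, y]
                        ):
                            seen[x, y] = True
                            stack.append((x, y))
                areas.append(size)
    return sorted(areas)


@pytest.mark.parametrize("adjacency", [4, 8])
@pytest.mark.parametrize("seed", range(10))
def test_cluster_finder_matches_flood_fill_oracle(seed, adjacency):
    rng = np.random.default_rng(seed)
    mask = rng.random((6, 6)) < 0.4
    got = sorted(int(c.sum()) for c in _clusters_from_mask(mask, adjacency))
    assert got == _flood_fill_areas(mask, adjacency)


def test_all_zero_z_produces_no_clusters():
    z = np.zeros((10, 6))
    ctm = _ctm_from_z(z, z.copy())
    ctm = cluster_test_2d(ctm, n_perm=50, seed=0)
    assert ctm.clusters == []


def test_cluster_test_2d_detects_shared_pattern():
    rng = np.random.default_rng(5)
    pattern = rng.normal(size=30)
    z_odd = pattern[:, None] + 0.3 * rng.normal(size=(30, 8))
    z_even = pattern[:, None] + 0.3 * rng.normal(size=(30, 8))
    ctm = _ctm_from_z(z_odd, z_even)
    ctm = cluster_test_2d(ctm, n_perm=300, seed=5)
    assert ctm.clusters and ctm.clusters[0].corrected_p < 0.05
    assert ctm.clusters[0].area >= 32  # most of the 64 pixels


def test_time_shuffle_null_mode_runs():
    rng = np.random.default_rng(6)
    ctm = _ctm_from_z(rng.normal(size=(12, 6)), rng.normal(size=(12, 6)))
    ctm = cluster_test_2d(ctm, n_perm=50, seed=1, null_mode="time")
    assert all(0 < c.corrected_p <= 1 for c in ctm.clusters)


# ---------------------------------------------------------------------------
# group comparison


def test_identical_groups_show_no_difference_pixels():
    rng = np.random.default_rng(7)
    z1, z2 = rng.normal(size=(12, 5)), rng.normal(size=(12, 5))
    a = _ctm_from_z(z1, z2)
    b = _ctm_from_z(z1.copy(), z2.copy())
    area, p, mask = compare_groups(a, b, n_perm=50, seed=0)
    assert area == 0 and not mask.any() and p == pytest.approx(1.0)


def test_grid_mismatch_rejected():
    rng = np.random.default_rng(8)
    a = _ctm_from_z(rng.normal(size=(8, 5)), rng.normal(size=(8, 5)))
    b = _ctm_from_z(rng.normal(size=(8, 7)), rng.normal(size=(8, 7)))
    with pytest.raises(ValueError, match="grid"):
        compare_groups(a, b, n_perm=10, seed=0)


def test_shared_vs_unshared_pattern_groups_differ():
    rng = np.random.default_rng(9)
    pattern = rng.normal(size=40)
    a = _ctm_from_z(
        pattern[:, None] + 0.3 * rng.normal(size=(40, 6)),
        pattern[:, None] + 0.3 * rng.normal(size=(40, 6)),
    )
    b = _ctm_from_z(rng.normal(size=(40, 6)), rng.normal(size=(40, 6)))
    area, p, _ = compare_groups(a, b, n_perm=300, seed=1)
    assert area > 0 and p < 0.05
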