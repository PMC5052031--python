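import numpy as np
import pytest
from scipy import stats

from nts.groupstats import (
    area_dispersion_tests,
    cluster_test_1d,
    median_split,
    rank_corr_at_peak,
    sorted_display_matrix,
    tau_cpd_regression,
)


# ---------------------------------------------------------------------------
# median split


def test_median_split_four_values():
    labels = median_split([1.0, 2.0, 3.0, 4.0])
    assert list(labels) == ["low", "low", "high", "high"]


def test_median_split_ties_go_low_and_odd_n():
    labels = median_split([1.0, 2.0, 3.0, 4.0, 5.0])
    assert (labels == "high").sum() == 2  # floor(n/2); the median goes low
    assert labels[2] == "low"


def test_median_split_degenerate_warns():
    with pytest.warns(UserWarning, match="degenerate"):
        labels = median_split([2.0, 2.0, 2.0])
    assert (labels == "low").all()


def test_median_split_within_areas():
    tau = np.array([1.0, 2.0, 10.0, 20.0])
    areas = np.array(["OFC", "OFC", "ACC", "ACC"])
    labels = median_split(tau, areas)
    assert list(labels) == ["low", "high", "low", "high"]


# ---------------------------------------------------------------------------
# 1-D cluster test


def test_identical_groups_give_no_cluster():
    rng = np.random.default_rng(0)
    a = rng.random((10, 50))
    res = cluster_test_1d(a, a.copy(), n_perm=200, seed=1)
    assert res.cluster_length == 0
    assert res.corrected_p == pytest.approx(1.0)
    assert res.cluster_window is None


def test_strong_group_difference_detected_inside_window():
    rng = np.random.default_rng(1)
    a = rng.normal(0.0, 1.0, (20, 60))
    b = rng.normal(0.0, 1.0, (20, 60))
    a[:, 20:35] += 3.0
    res = cluster_test_1d(a, b, window=(10, 50), n_perm=500, seed=2)
    assert res.corrected_p < 0.05 and res.significant_05
    lo, hi = res.cluster_window
    assert 10 <= lo and hi <= 50 and lo >= 18 and hi <= 37


def test_window_outside_range_rejected():
    a = np.zeros((3, 10))
    with pytest.raises(ValueError, match="window"):
        cluster_test_1d(a, a, window=(5, 20), n_perm=10, seed=0)


def test_cluster_test_needs_two_per_group():
    a = np.zeros((1, 10))
    with pytest.raises(ValueError, match="2 neurons"):
        cluster_test_1d(a, np.zeros((5, 10)), n_perm=10, seed=0)


def test_cluster_test_deterministic_given_seed():
    rng = np.random.default_rng(3)
    a, b = rng.random((8, 40)), rng.random((8, 40))
    r1 = cluster_test_1d(a, b, n_perm=300, seed=7)
    r2 = cluster_test_1d(a, b, n_perm=300, seed=7)
    assert r1.corrected_p == r2.corrected_p


# ---------------------------------------------------------------------------
# rank correlation at peak


def test_monotone_link_gives_rho_one():
    tau = np.linspace(0.1, 1.0, 20)
    cpd = np.tile(tau[:, None], (1, 30))  # CPD strictly increasing in tau
    link = rank_corr_at_peak(tau, cpd)
    assert link.rho == pytest.approx(1.0)


def test_constant_cpd_reports_degenerate_zero():
    link = rank_corr_at_peak(np.linspace(0.1, 1, 15), np.ones((15, 10)))
    assert link.rho == 0.0 and link.degenerate


def test_peak_tie_resolved_to_earliest_bin():
    rng = np.random.default_rng(4)
    cpd = rng.random((12, 6)) * 0.1
    cpd[:, 2] = 0.9
    cpd[:, 5] = 0.9  # exact tie in the population mean
    link = rank_corr_at_peak(np.linspace(0.1, 1, 12), cpd)
    assert link.peak_bin == 2


def test_fisher_ci_shrinks_with_n():
    rng = np.random.default_rng(5)
    for n, width in ((20, 0.8), (500, 0.2)):
        tau = np.linspace(0.1, 1.0, n)
        cpd = tau[:, None] + 0.3 * rng.random((n, 5))
        link = rank_corr_at_peak(tau, cpd)
        assert link.rho_ci[1] - link.rho_ci[0] < width


# ---------------------------------------------------------------------------
# regression with area controls


def test_exact_power_law_recovered():
    rng = np.random.default_rng(6)
    n = 90
    tau = np.exp(rng.normal(-1.5, 0.4, n))
    rate = np.exp(rng.normal(np.log(10.0), 0.3, n))
    areas = np.array(["DLPFC", "OFC", "ACC"] * (n // 3))
    cpd = tau**0.5
    table = tau_cpd_regression(tau, cpd, rate, areas)
    assert table.loc["log_tau", "coef"] == pytest.approx(0.5, abs=1e-8)
    assert table.loc["log_tau", "ci_low"] <= 0.5 <= table.loc["log_tau", "ci_high"]


def test_area_confound_attenuates_coefficient():
    rng = np.random.default_rng(7)
    n = 150
    areas = np.repeat(["DLPFC", "OFC", "ACC"], n // 3)
    area_shift = {"DLPFC": -0.5, "OFC": 0.0, "ACC": 0.5}
    tau = np.exp([area_shift[a] for a in areas] + 0.1 * rng.standard_normal(n) - 1.5)
    cpd = np.exp([2 * area_shift[a] for a in areas] + 0.2 * rng.standard_normal(n) - 4)
    rate = np.exp(rng.normal(np.log(10.0), 0.3, n))
    with_dummies = tau_cpd_regression(tau, cpd, rate, areas).loc["log_tau", "coef"]
    one_area = tau_cpd_regression(
        tau, cpd, rate, np.repeat(["OFC"], n)
    ).loc["log_tau", "coef"]
    assert abs(with_dummies) < abs(one_area)


def test_collinear_design_rejected():
    n = 30
    tau = np.exp(np.linspace(-2, -1, n))
    with pytest.raises(ValueError, match="collinear"):
        tau_cpd_regression(tau, tau**0.5, tau, np.repeat(["OFC"], n))


# ---------------------------------------------------------------------------
# area dispersion/location tests


def test_identical_area_samples_give_zero_kw_statistic():
    tau = np.tile(np.exp(np.linspace(-2, -1, 30)), 3)
    areas = np.repeat(["DLPFC", "OFC", "ACC"], 30)
    out = area_dispersion_tests(tau, areas)
    assert out["kruskal_stat"] == pytest.approx(0.0)
    assert out["bartlett_p"] == pytest.approx(1.0)


def test_null_pvalues_uniform_over_replicates():
    rng = np.random.default_rng(8)
    pb, pk = [], []
    for _ in range(300):
        tau = np.exp(rng.normal(-1.5, 0.5, 90))
        areas = np.repeat(["DLPFC", "OFC", "ACC"], 30)
        out = area_dispersion_tests(tau, areas)
        pb.append(out["bartlett_p"])
        pk.append(out["kruskal_p"])
    assert stats.kstest(pb, "uniform").pvalue > 0.01
    assert stats.kstest(pk, "uniform").pvalue > 0.01


def test_doubled_dispersion_detected_by_bartlett():
    rng = np.random.default_rng(9)
    hits = 0
    for _ in range(25):
        g1 = rng.normal(-1.5, 0.4, 150)
        g2 = rng.normal(-1.5, 0.8, 150)
        g3 = rng.normal(-1.5, 0.4, 150)
        tau = np.exp(np.concatenate([g1, g2, g3]))
        areas = np.repeat(["DLPFC", "OFC", "ACC"], 150)
        hits += area_dispersion_tests(tau, areas)["bartlett_p"] < 0.05
    assert hits >= 20


def test_small_area_excluded_with_warning():
    tau = np.exp(np.concatenate([np.linspace(-2, -1, 20), [-1.5, -1.4]]))
    areas = np.array(["OFC"] * 10 + ["DLPFC"] * 10 + ["ACC"] * 2)
    with pytest.warns(UserWarning, match="ACC"):
        out = area_dispersion_tests(tau, areas)
    assert np.isfinite(out["bartlett_stat"])


# ---------------------------------------------------------------------------
# sorted display matrix


def test_delta_row_smooths_to_discrete_gaussian():
    n = 41
    m = np.zeros((n, 3))
    m[20, :] = 1.0
    sm, order = sorted_display_matrix(m, np.arange(n, dtype=float))
    k = np.exp(-0.5 * (np.arange(-8, 9) / 2.0) ** 2)
    k /= k.sum()
    np.testing.assert_allclose(sm[12:29, 0], k, atol=1e-9)
    np.testing.assert_array_equal(order, np.arange(n))


def test_constant_matrix_unchanged_by_smoothing():
    m = np.full((25, 10), 3.14)
    sm, _ = sorted_display_matrix(m, np.arange(25, dtype=float))
    np.testing.assert_allclose(sm, m, atol=1e-12)


def test_grand_mean_conserved():
    rng = np.random.default_rng(10)
    m = rng.random((37, 20))
    sm, _ = sorted_display_matrix(m, rng.random(37))
    assert abs(sm.mean() - m.mean()) < 1e-9


def test_reversing_tau_order_flips_matrix_vertically():
    rng = np.random.default_rng(11)
    m = rng.random((30, 8))
    tau = np.linspace(0.1, 1.0, 30)
    ascending, _ = sorted_display_matrix(m, tau)
    descending, _ = sorted_display_matrix(m, -tau)
    np.testing.assert_allclose(descending, ascending[::-1], atol=1e-12)
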