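import numpy as np
import pytest

from nts.autocorr import (
    ACFProfile,
    InsufficientDataError,
    acf_matrix,
    compute_profile,
    find_fit_start,
    fit_exponential,
    objective_inclusion,
    population_fit,
    stationarity_filter,
)


def _exp_curve(tau, a, b, n=19, dt=0.05):
    lags = dt * np.arange(1, n + 1)
    return a * (np.exp(-lags / tau) + b), lags


# ---------------------------------------------------------------------------
# ACF matrix


def test_identical_columns_correlate_perfectly():
    rng = np.random.default_rng(0)
    counts = rng.poisson(3.0, (50, 20))
    counts[:, 7] = counts[:, 2]
    mat, _ = acf_matrix(counts)
    assert mat[2, 7] == pytest.approx(1.0)


def test_three_trial_toy_counts_perfect_lag1():
    mat, lag = acf_matrix(np.array([[1, 2], [2, 4], [3, 6]]))
    assert lag[0] == pytest.approx(1.0)


def test_independent_poisson_columns_have_tiny_correlations():
    rng = np.random.default_rng(1)
    mat, _ = acf_matrix(rng.poisson(2.0, (5000, 20)))
    off = mat[~np.eye(20, dtype=bool)]
    assert np.nanmax(np.abs(off)) < 0.05


def test_lag_collapse_equals_anti_diagonal_means():
    """lag_acf[k-1] must equal the mean over matrix entries at lag k."""
    rng = np.random.default_rng(2)
    counts = rng.poisson(2.0, (100, 20))
    mat, lag = acf_matrix(counts)
    for k in range(1, 20):
        vals = [mat[i, i + k] for i in range(20 - k)]
        assert lag[k - 1] == pytest.approx(np.nanmean(vals))


def test_zero_variance_column_yields_nan_cells():
    rng = np.random.default_rng(3)
    counts = rng.poisson(2.0, (30, 5))
    counts[:, 2] = 4
    mat, _ = acf_matrix(counts)
    assert np.isnan(mat[2, 0]) and np.isnan(mat[1, 2])
    assert np.isfinite(mat[0, 1])


def test_too_few_trials_rejected():
    with pytest.raises(InsufficientDataError):
        acf_matrix(np.ones((2, 20)))


# ---------------------------------------------------------------------------
# exponential fit


def test_noiseless_curve_recovered_exactly():
    y, lags = _exp_curve(0.2, 0.5, 0.1)
    fit = fit_exponential(y, lags=lags)
    assert fit.tau == pytest.approx(0.2, abs=1e-6)
    assert fit.A == pytest.approx(0.5, abs=1e-6)
    assert fit.B == pytest.approx(0.1, abs=1e-6)


def test_noisy_recovery_median_error_small():
    rng = np.random.default_rng(4)
    errs = []
    for _ in range(100):
        y, lags = _exp_curve(0.2, 0.5, 0.1)
        fit = fit_exponential(y + 0.02 * rng.standard_normal(len(y)), lags=lags)
        errs.append(abs(fit.tau - 0.2) / 0.2)
    assert np.median(errs) < 0.15


def test_fit_starts_where_largest_drop_lands():
    y, lags = _exp_curve(0.3, 0.5, 0.0)
    y[0] = y[1] + 0.2  # elevated first lag: the largest drop is 1 -> 2
    fit = fit_exponential(y, lags=lags)
    assert fit.fit_start_lag == 2
    assert lags[fit.fit_start_lag - 1] == pytest.approx(0.1)  # first point 100 ms


def test_first_drop_rule_differs_from_largest_drop():
    y = np.array([0.5, 0.48, 0.1, 0.08, 0.06, 0.05] + [0.04] * 13)
    assert find_fit_start(y, "first_drop") == 2
    assert find_fit_start(y, "largest_drop") == 3


def test_rescaling_acf_leaves_tau_invariant():
    rng = np.random.default_rng(5)
    y, lags = _exp_curve(0.25, 0.4, 0.2)
    y = y + 0.01 * rng.standard_normal(len(y))
    f1 = fit_exponential(y, lags=lags)
    f2 = fit_exponential(3.0 * y, lags=lags)
    assert f2.tau == pytest.approx(f1.tau, rel=1e-4)
    assert f2.A == pytest.approx(3.0 * f1.A, rel=1e-4)
    assert f2.B == pytest.approx(f1.B, abs=1e-4)


def test_too_few_points_flagged_poor_fit():
    y = np.full(19, np.nan)
    y[:3] = [0.3, 0.2, 0.1]
    fit = fit_exponential(y)
    assert not fit.included and fit.exclusion_reason == "poor_fit"


# ---------------------------------------------------------------------------
# inclusion screen


def _profile(lag_acf, rate=5.0, bin_totals=None):
    n = len(lag_acf) + 1
    return ACFProfile(
        neuron_id="n",
        bin_matrix=np.eye(n),
        lag_acf=np.asarray(lag_acf, dtype=float),
        n_trials_used=100,
        fixation_rate=rate,
        bin_totals=bin_totals if bin_totals is not None else np.ones(n),
    )


def test_low_rate_neuron_excluded():
    y, lags = _exp_curve(0.2, 0.5, 0.0)
    fit = fit_exponential(y, lags=lags)
    ok, reason = objective_inclusion(_profile(y, rate=0.5), fit)
    assert not ok and reason == "low_rate"


def test_flat_acf_excluded_as_no_decline():
    y = np.full(19, 0.3)
    ok, reason = objective_inclusion(_profile(y), fit_exponential(y))
    assert not ok and reason == "no_decline"


def test_late_drop_excluded_as_no_decline():
    y = np.concatenate([np.full(10, 0.30), np.full(9, 0.05)])  # drop at lag 11
    ok, reason = objective_inclusion(_profile(y), fit_exponential(y))
    assert not ok and reason == "no_decline"


def test_silent_bin_excluded():
    y, lags = _exp_curve(0.2, 0.5, 0.0)
    totals = np.ones(20)
    totals[4] = 0
    ok, reason = objective_inclusion(
        _profile(y, bin_totals=totals), fit_exponential(y, lags=lags)
    )
    assert not ok and reason == "zero_bin"


def test_negative_amplitude_excluded_by_default_sign_rule():
    y, lags = _exp_curve(0.2, -0.3, -1.5)  # rising curve, A < 0
    y[0] += 0.2  # give it an early "drop" so the sign rule is reached
    fit = fit_exponential(y, lags=lags)
    if fit.A <= 0:
        ok, reason = objective_inclusion(_profile(y), fit)
        assert not ok and reason == "sign_degenerate"


def test_strict_sign_rule_excludes_positive_a_and_b():
    y, lags = _exp_curve(0.2, 0.5, 0.3)
    fit = fit_exponential(y, lags=lags)
    ok, reason = objective_inclusion(_profile(y), fit, sign_rule="strict")
    assert not ok and reason == "sign_degenerate"
    ok, _ = objective_inclusion(_profile(y), fit, sign_rule="default")
    assert ok


def test_good_neuron_included():
    y, lags = _exp_curve(0.2, 0.5, 0.1)
    ok, reason = objective_inclusion(_profile(y), fit_exponential(y, lags=lags))
    assert ok and reason == "none"


# ---------------------------------------------------------------------------
# stationarity filter


def test_constant_counts_select_everything():
    sel = stationarity_filter(np.full(400, 5.0))
    assert sel.first == 0 and sel.last == 399 and sel.all_selected


def test_short_sessions_pass_through_flagged():
    sel = stationarity_filter(np.arange(50.0))
    assert sel.all_selected and sel.fraction_removed == 0.0


def test_stationary_poisson_removes_few_trials():
    rng = np.random.default_rng(8)
    sel = stationarity_filter(rng.poisson(8.0, 400).astype(float))
    assert sel.fraction_removed < 0.05


def test_step_change_confines_selection_to_one_side():
    rng = np.random.default_rng(0)
    x = np.concatenate([rng.poisson(5, 200), rng.poisson(15, 200)]).astype(float)
    sel = stationarity_filter(x)
    pre = max(0, min(sel.last, 199) - min(sel.first, 199) + 1) if sel.first <= 199 else 0
    post = max(0, sel.last - max(sel.first, 200) + 1) if sel.last >= 200 else 0
    # the KW window cannot flag a handful of contaminated trials, so allow
    # a small overhang; the far side must be essentially excluded
    assert min(pre, post) <= 0.05 * len(x)


def test_monotone_drift_everything_fails_falls_back():
    x = np.arange(400.0) * 10
    with pytest.warns(UserWarning, match="no stationary"):
        sel = stationarity_filter(x)
    assert sel.degenerate and (sel.last - sel.first + 1) == 100


# ---------------------------------------------------------------------------
# population fit


def test_population_of_identical_neurons_matches_single_fit():
    y, lags = _exp_curve(0.3, 0.5, 0.05)
    profs = {f"n{i}": _profile(y) for i in range(4)}
    fits = population_fit(profs, {f"n{i}": "OFC" for i in range(4)})
    single = fit_exponential(y, lags=lags)
    assert fits["OFC"].tau == pytest.approx(single.tau, rel=1e-6)


def test_all_nan_profile_is_ignored_in_population_mean():
    y, _ = _exp_curve(0.3, 0.5, 0.05)
    profs = {"a": _profile(y), "b": _profile(np.full(19, np.nan))}
    fits = population_fit(profs, {"a": "OFC", "b": "OFC"})
    assert fits["OFC"].tau == pytest.approx(fit_exponential(y).tau, rel=1e-6)


def test_cohort_table_has_expected_columns(small_coding_dataset):
    from nts.autocorr import analyze_cohort

    _, ds, _ = small_coding_dataset
    tab, profiles = analyze_cohort(ds)
    assert {"neuron_id", "tau", "A", "B", "included", "exclusion_reason"} <= set(
        tab.columns
    )
    assert len(tab) == len(ds.neurons)
    assert set(profiles) == set(ds.neuron_ids)
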