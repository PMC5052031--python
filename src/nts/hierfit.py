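"""Hierarchical (random-effects) timescale assignment by EM.

Each included neuron contributes its lag ACF from the fit-start lag
onwards; the observation model is the exponential decay curve plus i.i.d.
Gaussian noise with a per-neuron variance.  The per-neuron parameters
theta = (log tau, A, B) are treated as draws from a population-level
multivariate Gaussian N(mu, Sigma), estimated by expectation–maximisation:

* **E-step** — per neuron, the MAP of theta under the current prior
  (a penalised nonlinear least-squares problem), with a Laplace (Gauss–
  Newton) approximation to the posterior covariance; the exact posterior
  is intractable under the nonlinear curve.
* **M-step** — mu and Sigma from the approximate posterior means and
  covariances; per-neuron noise variances from the residuals.

Convergence is monitored through a variational lower-bound proxy for the
marginal likelihood (Gaussian q at the Laplace point); the trace is
reported and should be non-decreasing to numerical tolerance.  Shrinkage
behaves as expected for a random-effects model: noisy neurons move farther
toward the population mean than clean ones.

By default the hierarchical stage starts each neuron's curve at the *first*
reduction of the ACF between consecutive lags, whereas the single-neuron
least-squares stage starts at the *largest* reduction; the two conventions
are kept distinct on purpose (``start_rule`` unifies them if desired).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .autocorr import ACFProfile, ExponentialFit, find_fit_start, fit_exponential


@dataclass
class PopulationPrior:
    mu: np.ndarray  # (3,) mean of (log tau, A, B)
    sigma: np.ndarray  # (3, 3) covariance

    def __post_init__(self) -> None:
        self.sigma = 0.5 * (self.sigma + self.sigma.T)


@dataclass
class HierarchicalResult:
    neuron_ids: list[str]
    theta_map: np.ndarray  # n × 3 MAP (log tau, A, B)
    theta_cov: np.ndarray  # n × 3 × 3 Laplace posterior covariances
    sigma2: np.ndarray  # n per-neuron observation noise variances
    prior: PopulationPrior
    loglik_trace: list[float] = field(default_factory=list)
    n_iterations: int = 0
    converged: bool = False

    @property
    def tau(self) -> np.ndarray:
        return np.exp(self.theta_map[:, 0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "neuron_id": self.neuron_ids,
                "tau": self.tau,
                "log_tau": self.theta_map[:, 0],
                "A": self.theta_map[:, 1],
                "B": self.theta_map[:, 2],
                "sigma2": self.sigma2,
            }
        )


def _model(theta: np.ndarray, lags: np.ndarray) -> np.ndarray:
    logtau, a, b = theta
    return a * (np.exp(-lags / np.exp(logtau)) + b)


def _jacobian(theta: np.ndarray, lags: np.ndarray) -> np.ndarray:
    logtau, a, b = theta
    tau = np.exp(logtau)
    e = np.exp(-lags / tau)
    return np.column_stack([a * e * lags / tau, e + b, np.full_like(lags, a)])


def prepare_curves(
    profiles: dict[str, ACFProfile], start_rule: str = "first_drop"
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Extract (lags, acf) fit windows for the hierarchical stage."""
    curves = {}
    for nid, prof in profiles.items():
        start = find_fit_start(prof.lag_acf, start_rule)
        sel = np.arange(start - 1, len(prof.lag_acf))
        sel = sel[np.isfinite(prof.lag_acf[sel])]
        if len(sel) >= 4:
            curves[nid] = (prof.lags[sel], prof.lag_acf[sel])
    return curves


def _map_step(
    lags: np.ndarray,
    y: np.ndarray,
    sigma2: float,
    prior: PopulationPrior,
    theta0: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Penalised LS: MAP theta, Laplace covariance, residual sum of squares."""
    sigma_inv = np.linalg.inv(prior.sigma)
    l_prior = np.linalg.cholesky(sigma_inv).T  # L theta penalty, L^T L = Sigma^-1
    s = np.sqrt(sigma2)

    def resid(th):
        return np.concatenate([(_model(th, lags) - y) / s, l_prior @ (th - prior.mu)])

    def jac(th):
        return np.vstack([_jacobian(th, lags) / s, l_prior])

    # B is left unbounded below (unlike the single-neuron LS stage): the
    # Gaussian population prior regularises it smoothly, avoiding the
    # boundary pile-up that biases tau when B is floored at zero.
    lo = np.array([np.log(1e-3), -10.0, -2.0])
    hi = np.array([np.log(10.0), 10.0, 2.0])
    res = least_squares(
        resid, np.clip(theta0, lo + 1e-9, hi - 1e-9), jac=jac, bounds=(lo, hi),
        method="trf", max_nfev=200,
    )
    j = jac(res.x)
    h = j.T @ j  # Gauss-Newton posterior precision
    cov = np.linalg.inv(h + 1e-10 * np.eye(3))
    rss = float(np.sum((_model(res.x, lags) - y) ** 2))
    return res.x, cov, rss


def _elbo(
    curves: list[tuple[np.ndarray, np.ndarray]],
    theta: np.ndarray,
    cov: np.ndarray,
    sigma2: np.ndarray,
    prior: PopulationPrior,
) -> float:
    """Variational lower bound with Gaussian q at the Laplace point."""
    sigma_inv = np.linalg.inv(prior.sigma)
    _, logdet_prior = np.linalg.slogdet(prior.sigma)
    total = 0.0
    for i, (lags, y) in enumerate(curves):
        n = len(y)
        j = _jacobian(theta[i], lags)
        rss = float(np.sum((_model(theta[i], lags) - y) ** 2))
        trace_term = float(np.trace(j @ cov[i] @ j.T))
        total += -0.5 * n * np.log(2 * np.pi * sigma2[i]) - (rss + trace_term) / (
            2 * sigma2[i]
        )
        d = theta[i] - prior.mu
        total += -0.5 * (3 * np.log(2 * np.pi) + logdet_prior)
        total += -0.5 * (d @ sigma_inv @ d + float(np.trace(sigma_inv @ cov[i])))
        _, logdet_q = np.linalg.slogdet(cov[i])
        total += 0.5 * (3 * (1 + np.log(2 * np.pi)) + logdet_q)  # entropy of q
    return total


def em_fit(
    profiles: dict[str, ACFProfile],
    start_rule: str = "first_drop",
    init: PopulationPrior | None = None,
    tol: float = 1e-6,
    max_iter: int = 50,
    update_prior: bool = True,
    min_sigma2: float = 1e-8,
    ridge: float = 1e-6,
) -> HierarchicalResult:
    """Fit the hierarchical model to one area's included neurons.

    ``update_prior=False`` freezes (mu, Sigma) at ``init`` — with a vague
    init this reduces every neuron to its own least-squares fit, which is
    the standard sanity limit of a random-effects model.
    """
    curves_d = prepare_curves(profiles, start_rule)
    if len(curves_d) < 1:
        raise ValueError("no usable ACF curves for hierarchical fit")
    if len(curves_d) < 5 and update_prior:
        warnings.warn("fewer than 5 neurons: population prior will be weak")
    neuron_ids = list(curves_d)
    curves = [curves_d[n] for n in neuron_ids]
    n_neurons = len(curves)

    # initialisation from per-neuron least-squares fits
    theta = np.zeros((n_neurons, 3))
    sigma2 = np.zeros(n_neurons)
    for i, (lags, y) in enumerate(curves):
        # curves are already windowed: fit every point, no re-cutting
        ls = fit_exponential(
            y, lags=lags, start_rule="none", b_bounds=(-2.0, 2.0), min_points=4
        )
        if np.isfinite(ls.tau):
            theta[i] = [np.log(ls.tau), ls.A, ls.B]
            sigma2[i] = max(ls.sse / max(len(y) - 3, 1), min_sigma2)
        else:
            theta[i] = [np.log(0.2), 0.3, 0.0]
            sigma2[i] = max(np.var(y), min_sigma2)
    if init is not None:
        prior = PopulationPrior(init.mu.copy(), init.sigma.copy())
    else:
        mu0 = np.median(theta, axis=0)
        mad = np.median(np.abs(theta - mu0), axis=0)
        spread = np.maximum((1.4826 * mad) ** 2, 1e-3)
        prior = PopulationPrior(mu0, np.diag(spread))

    cov = np.zeros((n_neurons, 3, 3))
    trace: list[float] = []
    converged = False
    it = 0
    snapshot = None
    for it in range(1, max_iter + 1):
        # E-step: per-neuron MAP + Laplace covariance
        for i, (lags, y) in enumerate(curves):
            theta[i], cov[i], rss = _map_step(lags, y, sigma2[i], prior, theta[i])
            j = _jacobian(theta[i], lags)
            sigma2[i] = max(
                (rss + float(np.trace(j @ cov[i] @ j.T))) / len(y), min_sigma2
            )
        # M-step: population Gaussian from approximate posteriors
        if update_prior:
            mu = theta.mean(axis=0)
            d = theta - mu
            sig = (cov.sum(axis=0) + d.T @ d) / n_neurons
            if np.linalg.cond(sig) > 1e10:
                warnings.warn("population covariance near-singular; ridge added")
                sig = sig + ridge * np.eye(3)
            prior = PopulationPrior(mu, sig)
        elbo = _elbo(curves, theta, cov, sigma2, prior)
        if trace and elbo < trace[-1]:
            # the Laplace approximation no longer improves the proxy:
            # revert to the previous (best) iterate and stop
            theta, cov, sigma2, prior = snapshot
            converged = True
            break
        snapshot = (theta.copy(), cov.copy(), sigma2.copy(), prior)
        trace.append(elbo)
        if len(trace) >= 2 and abs(trace[-1] - trace[-2]) < tol * max(1.0, abs(trace[-2])):
            converged = True
            break
    return HierarchicalResult(
        neuron_ids=neuron_ids,
        theta_map=theta,
        theta_cov=cov,
        sigma2=sigma2,
        prior=prior,
        loglik_trace=trace,
        n_iterations=it,
        converged=converged,
    )


def em_fit_by_area(
    profiles: dict[str, ACFProfile],
    area_of: dict[str, str],
    **kwargs,
) -> dict[str, HierarchicalResult]:
    """Run :func:`em_fit` separately for the neurons of each area."""
    by_area: dict[str, dict[str, ACFProfile]] = {}
    for nid, prof in profiles.items():
        by_area.setdefault(area_of[nid], {})[nid] = prof
    out = {}
    for area, profs in by_area.items():
        try:
            out[area] = em_fit(profs, **kwargs)
        except ValueError as exc:
            warnings.warn(f"area {area}: {exc}")
    return out
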