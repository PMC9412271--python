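"""Pure mathematical kernel: detection function, link, and the three
submodel log-likelihood contributions.

This module is the readable numpy/scipy reference implementation. The MCMC
sampler uses equivalent numba kernels (:mod:`scrim._kernels`) that are tested
against these functions.

The detection model is a half-normal encounter rate

    lambda_ij = lam0 * exp(-d_ij^2 / (2 sigma^2))

converted to a per-occasion detection probability through the complementary
log-log link p = 1 - exp(-lambda). A useful identity used throughout:
log(1 - p_ij) = -lambda_ij.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from scipy.special import gammaln

from .types import AugmentedState, OccData, SCRData, TelemetryData, TrapArray

__all__ = [
    "encounter_rate",
    "rate_to_prob",
    "pairwise_sq_dist",
    "detection_prob",
    "trap_rates",
    "scr_loglik",
    "occ_det_prob",
    "occ_loglik",
    "telemetry_loglik",
    "telemetry_sigma_profile_mle",
]


def encounter_rate(d, lam0, sigma):
    """Half-normal encounter rate at distance ``d`` (km).

    Parameters
    ----------
    d : array_like
        Euclidean distance(s) between trap and activity center, km, >= 0.
    lam0 : float
        Baseline encounter rate per occasion at distance zero, >= 0.
    sigma : float
        Half-normal spatial scale, km, > 0.

    Returns
    -------
    ndarray or float
        lam0 * exp(-d^2 / (2 sigma^2)); nonincreasing in ``d``.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if lam0 < 0:
        raise ValueError("lam0 must be nonnegative")
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance must be nonnegative")
    out = lam0 * np.exp(-(d**2) / (2.0 * sigma**2))
    return out if out.ndim else float(out)


def rate_to_prob(lam):
    """Complementary log-log link: p = 1 - exp(-lambda).

    Strictly increasing, maps [0, inf) onto [0, 1).
    """
    lam = np.asarray(lam, dtype=float)
    if np.any(lam < 0):
        raise ValueError("encounter rate must be nonnegative")
    out = -np.expm1(-lam)
    return out if out.ndim else float(out)


def pairwise_sq_dist(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Squared Euclidean distances between rows of ``a`` (n,2) and ``b`` (m,2)."""
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    diff = a[:, None, :] - b[None, :, :]
    return np.einsum("ijk,ijk->ij", diff, diff)


def _lam0_per_trap(state: AugmentedState, traps: TrapArray) -> np.ndarray:
    """Per-trap baseline rate, honouring the bait covariate when switched in."""
    if state.w and traps.bait is not None:
        return np.exp(state.beta0 + state.beta1 * traps.bait)
    return np.full(traps.n_traps, state.lam0_trap)


def trap_rates(s: np.ndarray, coords: np.ndarray, lam0, sigma: float) -> np.ndarray:
    """Encounter-rate matrix lambda[i, j] for centers ``s`` against detectors."""
    d2 = pairwise_sq_dist(s, coords)
    return np.asarray(lam0) * np.exp(-d2 / (2.0 * sigma**2))


def detection_prob(s: np.ndarray, coords: np.ndarray, lam0, sigma: float) -> np.ndarray:
    """Per-occasion detection probability matrix p[i, j]."""
    return -np.expm1(-trap_rates(s, coords, lam0, sigma))


def scr_loglik(state: AugmentedState, traps: TrapArray, data: SCRData) -> float:
    """Binomial SCR log-likelihood over observed and augmented individuals.

    The first ``n = data.n_individuals`` augmented slots hold the observed
    rows; each contributes Binomial(K_j, p_ij) mass for its counts. The
    remaining M - n slots contribute the all-zero mass (K_j log(1 - p_ij)
    summed over traps, i.e. -sum_j K_j lambda_ij) when z_i = 1 and nothing
    when z_i = 0.
    """
    data.validate_against(traps)
    n = data.n_individuals
    if n > state.M:
        raise ValueError("more observed individuals than augmented slots")
    lam0j = _lam0_per_trap(state, traps)
    lam = trap_rates(state.s, traps.coords, lam0j[None, :], state.sigma)
    K = traps.effort
    ll = 0.0
    if n:
        y = data.y
        p = -np.expm1(-lam[:n])
        with np.errstate(divide="ignore", invalid="ignore"):
            logp = np.where(y > 0, np.log(np.where(p > 0, p, 1.0)), 0.0)
        if np.any((data.y > 0) & (p == 0.0)):
            return -np.inf
        ll += float(
            np.sum(
                gammaln(K[None, :] + 1)
                - gammaln(y + 1)
                - gammaln(K[None, :] - y + 1)
                + y * logp
                - (K[None, :] - y) * lam[:n]
            )
        )
    if state.M > n:
        zero_mass = -(lam[n:] * K[None, :]).sum(axis=1)  # log of all-zero binomial mass
        ll += float(np.sum(state.z[n:] * zero_mass))
    return ll


def occ_det_prob(state: AugmentedState, cameras: TrapArray, camera_j=None):
    """Occasion-level detection probability at camera(s) ``camera_j``.

    1 - prod_i (1 - p_ij)^{z_i}; with the cloglog link this equals
    1 - exp(-sum_{i: z_i=1} lambda_ij).
    """
    lam = trap_rates(state.s, cameras.coords, state.lam0_cam, state.sigma)
    total = state.z @ lam
    q = -np.expm1(-total)
    if camera_j is None:
        return q
    return float(q[camera_j]) if np.isscalar(camera_j) else q[camera_j]


def occ_loglik(state: AugmentedState, cameras: TrapArray, data: OccData) -> float:
    """Binomial log-likelihood of per-camera detection counts.

    y_occ[j] ~ Binomial(K_j, 1 - prod_i (1 - p_ij)^{z_i}).
    """
    data.validate_against(cameras)
    q = occ_det_prob(state, cameras)
    K = cameras.effort
    y = data.y
    if np.any((y > 0) & (q <= 0.0)):
        return -np.inf
    with np.errstate(divide="ignore"):
        logq = np.where(y > 0, np.log(np.where(q > 0, q, 1.0)), 0.0)
    log1mq = np.log1p(-np.clip(q, 0.0, 1.0 - 1e-300))
    ll = (
        gammaln(K + 1)
        - gammaln(y + 1)
        - gammaln(K - y + 1)
        + y * logq
        + (K - y) * log1mq
    )
    return float(ll.sum())


def telemetry_loglik(state: AugmentedState, tel: TelemetryData) -> float:
    """Bivariate-normal (diagonal, shared sigma) log-density of all fixes.

    Each fix l_ir ~ BVN(s_i, sigma^2 I); tagged individual i occupies the
    augmented slot ``tel.links[i]``.
    """
    if state.sigma <= 0:
        raise ValueError("sigma must be positive")
    ll = 0.0
    for fixes, slot in zip(tel.fixes, tel.links):
        mu = state.s[slot]
        ll += float(stats.norm.logpdf(fixes[:, 0], mu[0], state.sigma).sum())
        ll += float(stats.norm.logpdf(fixes[:, 1], mu[1], state.sigma).sum())
    return ll


def telemetry_sigma_profile_mle(tel: TelemetryData) -> float:
    """Closed-form profile MLE of sigma from telemetry alone.

    Maximizing over each s_i puts it at the fix centroid; the profile
    maximizer is sigma_hat^2 = sum_i sum_r ||l_ir - centroid_i||^2 / (2 sum_i R_i)
    (the factor 2 counts both coordinate axes).
    """
    ssq = tel.sum_sq_dev().sum()
    total_fixes = int(tel.n_fixes.sum())
    return float(np.sqrt(ssq / (2.0 * total_fixes)))
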