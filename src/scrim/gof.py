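"""Posterior-predictive goodness-of-fit for the SCR observation model.

Three discrepancy statistics, each compared between the observed data and a
replicate simulated from the same posterior draw (conditioning on that draw's
z and s): individual-by-trap frequencies, individual encounter frequencies
(row sums), and trap encounter frequencies (column sums). The Bayesian
p-value is the proportion of draws whose replicate discrepancy exceeds the
observed one (ties count one half).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .inference import ChainOutput
from .types import DataBundle

FLAVORS = ("ind_trap", "ind_freq", "trap_freq")

__all__ = ["GofResult", "discrepancy", "posterior_predictive_check", "FLAVORS"]


@dataclass
class GofResult:
    """Paired (observed, replicate) discrepancies per draw and the BPV."""

    flavor: str
    observed: np.ndarray
    replicated: np.ndarray
    bpv: float

    @property
    def n_draws(self) -> int:
        return self.observed.size


def discrepancy(
    obs: np.ndarray,
    expected: np.ndarray,
    flavor: str = "ind_trap",
    functional: str = "freeman_tukey",
) -> float:
    """Discrepancy between counts and expectations at one aggregation level.

    ``ind_trap`` uses the individual x trap cells; ``ind_freq`` the per-
    individual row sums; ``trap_freq`` the per-trap column sums. The default
    functional is Freeman-Tukey, sum (sqrt(obs) - sqrt(exp))^2; ``chisq``
    gives sum (obs - exp)^2 / (exp + 0.5).
    """
    obs = np.asarray(obs, dtype=float)
    expected = np.asarray(expected, dtype=float)
    if np.any(obs < 0) or np.any(expected < 0):
        raise ValueError("counts and expectations must be nonnegative")
    if flavor not in FLAVORS:
        raise ValueError(f"flavor must be one of {FLAVORS}")
    if flavor == "ind_freq":
        obs, expected = obs.sum(axis=-1), expected.sum(axis=-1)
    elif flavor == "trap_freq":
        obs, expected = obs.sum(axis=-2), expected.sum(axis=-2)
    if functional == "freeman_tukey":
        return float(((np.sqrt(obs) - np.sqrt(expected)) ** 2).sum())
    if functional == "chisq":
        return float(((obs - expected) ** 2 / (expected + 0.5)).sum())
    raise ValueError(f"unknown discrepancy functional {functional!r}")


def posterior_predictive_check(
    chains: ChainOutput,
    bundle: DataBundle,
    n_draws: int = 500,
    seed: int = 0,
    functional: str = "freeman_tukey",
    rhat_warn: float = 1.1,
) -> dict:
    """Simulate replicate SCR data from posterior draws and score all flavors.

    Each sampled draw contributes a (observed, replicate) discrepancy pair per
    statistic; replicates condition on the draw's latent state (z, s) and
    parameters, i.e. they are posterior predictive for the observation
    process. Returns ``{flavor: GofResult}``.
    """
    n_chains, n_snap, M = chains.latent_z.shape
    if n_snap == 0:
        raise ValueError("chains carry no latent snapshots; refit with latent_thin > 0")
    total = n_chains * n_snap
    if n_draws > total:
        raise ValueError(f"n_draws={n_draws} exceeds the {total} stored latent snapshots")

    import warnings as _warnings

    try:
        from .inference import summarize

        summ = summarize(chains)
        if np.nanmax(summ.table["rhat"].to_numpy()) > rhat_warn:
            _warnings.warn(
                "chains may not have converged (max Rhat > %.2f); "
                "goodness-of-fit results may be unreliable" % rhat_warn,
                RuntimeWarning,
                stacklevel=2,
            )
    except Exception:  # diagnostics failure should not block the check
        pass

    rng = np.random.default_rng(seed)
    flat = rng.choice(total, size=n_draws, replace=False)
    lt = max(chains.latent_thin, 1)

    coords = bundle.traps.coords
    K = bundle.traps.effort
    n = bundle.scr.n_individuals
    J = coords.shape[0]
    y_obs_full = np.zeros((M, J))
    y_obs_full[:n] = bundle.scr.y

    obs_disc = {f: np.empty(n_draws) for f in FLAVORS}
    rep_disc = {f: np.empty(n_draws) for f in FLAVORS}

    for d, fl in enumerate(flat):
        c, snap = divmod(int(fl), n_snap)
        it = snap * lt  # kept-iteration index of this snapshot
        sigma = chains.draws["sigma"][c, it]
        lam0 = chains.draws["lam0_trap"][c, it]
        z = chains.latent_z[c, snap].astype(float)
        s = chains.latent_s[c, snap]
        diff = s[:, None, :] - coords[None, :, :]
        lam = lam0 * np.exp(-np.einsum("ijk,ijk->ij", diff, diff) / (2 * sigma**2))
        p = -np.expm1(-lam)
        e = z[:, None] * K[None, :] * p
        y_rep = rng.binomial(K[None, :], p) * z[:, None].astype(int)
        for f in FLAVORS:
            obs_disc[f][d] = discrepancy(y_obs_full, e, f, functional)
            rep_disc[f][d] = discrepancy(y_rep, e, f, functional)

    out = {}
    for f in FLAVORS:
        gt = rep_disc[f] > obs_disc[f]
        eq = rep_disc[f] == obs_disc[f]
        bpv = float(gt.mean() + 0.5 * eq.mean())
        out[f] = GofResult(flavor=f, observed=obs_disc[f], replicated=rep_disc[f], bpv=bpv)
    return out
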