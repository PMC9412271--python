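"""Metropolis-within-Gibbs fitting of the integrated SCR model.

Four model variants share one augmented state: ``scr``, ``scr_occ``,
``scr_tel``, ``scr_occ_tel`` (plus a ``tel`` diagnostic variant that uses the
telemetry likelihood alone). Production sampling runs through the numba
kernels in :mod:`scrim._kernels`; this module also carries slow, readable
reference implementations of every update block (``update_z``, ``update_s``,
``update_params``, ``rj_update_covariate``) that the test suite cross-checks
against enumeration oracles and against the kernels.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from . import _kernels, model_core
from .types import AugmentedState, DataBundle, StateSpace

logger = logging.getLogger(__name__)

VARIANTS = ("scr", "scr_occ", "scr_tel", "scr_occ_tel")
_ALL_VARIANTS = VARIANTS + ("tel",)

__all__ = [
    "FitConfig",
    "PriorConfig",
    "ChainOutput",
    "PosteriorSummary",
    "joint_log_posterior",
    "update_z",
    "update_s",
    "update_params",
    "rj_update_covariate",
    "run_fit",
    "summarize",
    "cv_reduction",
    "half_sample_mode",
    "VARIANTS",
]


@dataclass(frozen=True)
class PriorConfig:
    """Vague priors in the standard BUGS SCR idiom (all configurable)."""

    psi_a: float = 1.0
    psi_b: float = 1.0
    sigma_max: float = 5.0  # sigma ~ Uniform(0, sigma_max) km
    lam0_max: float = 1.0  # lam0 ~ Uniform(0, lam0_max) per detector class
    beta_sd: float = 10.0  # beta ~ Normal(0, beta_sd)
    rj_proposal_sd: float = 1.0  # RJ birth proposal for beta1
    # RJ prior inclusion probability is fixed at 0.5 (prior odds 1)


@dataclass
class FitConfig:
    """Sampler configuration.

    ``n_iter`` is the number of *retained* iterations per chain, run after
    ``n_burn`` burn-in iterations (the only phase in which proposal scales
    adapt). Defaults follow the simulation protocol (3 chains of 6000 after
    1000 burn-in); the case-study protocol is 3 x 50,000 after 10,000.
    """

    M: int = 200
    n_chains: int = 3
    n_iter: int = 6000
    n_burn: int = 1000
    seed: int = 0
    variant: str = "scr_occ_tel"
    covariate_selection: bool = False
    priors: PriorConfig = field(default_factory=PriorConfig)
    latent_thin: int = 0  # 0 -> auto (~400 snapshots per chain)
    sigma_init: float = 0.6
    lam0_init: float = 0.05
    step_s: float = 0.5
    step_sigma: float = 0.15
    step_lam0: float = 0.3
    step_beta: float = 0.3

    def __post_init__(self) -> None:
        if self.variant not in _ALL_VARIANTS:
            raise ValueError(
                f"unknown variant {self.variant!r}; valid: {', '.join(_ALL_VARIANTS)}"
            )
        if self.n_iter < 0:
            raise ValueError("n_iter must be >= 0")
        if self.n_burn < 0:
            raise ValueError("n_burn must be >= 0")


def _variant_flags(variant: str) -> tuple[bool, bool, bool]:
    use_scr = variant != "tel"
    use_occ = "occ" in variant
    use_tel = variant.endswith("tel") and variant != "scr"  # tel, scr_tel, scr_occ_tel
    return use_scr, use_occ, use_tel


# ---------------------------------------------------------------------------
# joint posterior (reference)


def joint_log_posterior(
    state: AugmentedState,
    bundle: DataBundle,
    variant: str = "scr_occ_tel",
    priors: PriorConfig = PriorConfig(),
) -> float:
    """Reference log posterior (up to a constant) of the augmented state.

    Likelihood terms per variant plus: z | psi, psi ~ Beta, s ~ Uniform(S)
    (constant, omitted), uniform priors on sigma and the lam0s, normal priors
    on beta when the covariate is in the model.
    """
    use_scr, use_occ, use_tel = _variant_flags(variant)
    if use_occ and bundle.occ is None:
        raise ValueError(f"variant {variant!r} requires occupancy data")
    if use_tel and bundle.telemetry is None:
        raise ValueError(f"variant {variant!r} requires telemetry data")
    if not (0 < state.sigma < priors.sigma_max):
        return -np.inf
    if not (0 <= state.lam0_trap <= priors.lam0_max):
        return -np.inf
    if use_occ and not (0 <= state.lam0_cam <= priors.lam0_max):
        return -np.inf

    lp = 0.0
    n1 = state.N
    lp += n1 * np.log(state.psi) + (state.M - n1) * np.log1p(-state.psi)
    lp += stats.beta.logpdf(state.psi, priors.psi_a, priors.psi_b)
    if state.w:
        lp += stats.norm.logpdf(state.beta1, 0.0, priors.beta_sd)

    if use_scr:
        lp += model_core.scr_loglik(state, bundle.traps, bundle.scr)
    if use_occ:
        lp += model_core.occ_loglik(state, bundle.cameras, bundle.occ)
    if use_tel:
        lp += model_core.telemetry_loglik(state, bundle.telemetry)
    return float(lp)


# ---------------------------------------------------------------------------
# reference update blocks (slow; used on toys and in correctness tests)


def _latent_zero_loglik(state, bundle, i, use_scr, use_occ) -> float:
    """log L_i(z_i=1) - log L_i(z_i=0) for an unobserved individual."""
    delta = 0.0
    if use_scr:
        lam = model_core.trap_rates(
            state.s[i : i + 1], bundle.traps.coords, state.lam0_trap, state.sigma
        )[0]
        delta += -float((bundle.traps.effort * lam).sum())
    if use_occ:
        z1 = state.copy()
        z1.z[i] = 1
        z0 = state.copy()
        z0.z[i] = 0
        delta += model_core.occ_loglik(z1, bundle.cameras, bundle.occ) - model_core.occ_loglik(
            z0, bundle.cameras, bundle.occ
        )
    return delta


def update_z(
    state: AugmentedState,
    bundle: DataBundle,
    rng: np.random.Generator,
    variant: str = "scr_occ_tel",
) -> AugmentedState:
    """Gibbs draw of each unobserved z_i from its full conditional.

    P(z_i=1 | ...) = psi L_i / (psi L_i + 1 - psi) with L_i the individual's
    all-zero SCR mass times its occupancy contribution ratio.
    """
    use_scr, use_occ, _ = _variant_flags(variant)
    new = state.copy()
    for i in range(state.n_obs, state.M):
        delta = _latent_zero_loglik(new, bundle, i, use_scr, use_occ)
        logit = np.log(new.psi) - np.log1p(-new.psi) + delta
        new.z[i] = int(rng.uniform() < expit(logit))
    return new


def update_s(
    state: AugmentedState,
    bundle: DataBundle,
    rng: np.random.Generator,
    variant: str = "scr_occ_tel",
    step: float = 0.5,
) -> AugmentedState:
    """Per-individual random-walk Metropolis on the activity centers.

    Unobserved slots with z_i = 0 are refreshed from the uniform prior (their
    exact full conditional); proposals outside the state space are rejected.
    """
    use_scr, use_occ, use_tel = _variant_flags(variant)
    new = state.copy()
    space = bundle.space
    tel_slots = {}
    if use_tel and bundle.telemetry is not None:
        tel_slots = {int(l): k for k, l in enumerate(bundle.telemetry.links)}
    for i in range(state.M):
        if i >= state.n_obs and new.z[i] == 0:
            new.s[i] = space.sample(1, rng)[0]
            continue
        prop = new.s[i] + step * rng.standard_normal(2)
        if not space.contains(prop[None, :])[0]:
            continue
        cur = _individual_loglik(new, bundle, i, use_scr, use_occ, tel_slots)
        trial = new.copy()
        trial.s[i] = prop
        alt = _individual_loglik(trial, bundle, i, use_scr, use_occ, tel_slots)
        if np.log(rng.uniform()) < alt - cur:
            new.s[i] = prop
    return new


def _individual_loglik(state, bundle, i, use_scr, use_occ, tel_slots) -> float:
    """All likelihood terms that involve s_i (toy-scale; recomputes globals)."""
    ll = 0.0
    if use_scr:
        if i < state.n_obs:
            lam = model_core.trap_rates(
                state.s[i : i + 1], bundle.traps.coords, state.lam0_trap, state.sigma
            )[0]
            p = -np.expm1(-lam)
            y = bundle.scr.y[i]
            K = bundle.traps.effort
            if np.any((y > 0) & (p <= 0)):
                return -np.inf
            with np.errstate(divide="ignore"):
                ll += float(
                    np.sum(np.where(y > 0, y * np.log(np.where(p > 0, p, 1.0)), 0.0))
                    - np.sum((K - y) * lam)
                )
        elif state.z[i] == 1:
            lam = model_core.trap_rates(
                state.s[i : i + 1], bundle.traps.coords, state.lam0_trap, state.sigma
            )[0]
            ll += -float((bundle.traps.effort * lam).sum())
    if use_occ and state.z[i] == 1:
        ll += model_core.occ_loglik(state, bundle.cameras, bundle.occ)
    if i in tel_slots:
        fixes = bundle.telemetry.fixes[tel_slots[i]]
        ll += -float(((fixes - state.s[i]) ** 2).sum()) / (2.0 * state.sigma**2)
    return ll


def update_params(
    state: AugmentedState,
    bundle: DataBundle,
    rng: np.random.Generator,
    variant: str = "scr_occ_tel",
    priors: PriorConfig = PriorConfig(),
    step_sigma: float = 0.15,
    step_lam0: float = 0.3,
) -> AugmentedState:
    """psi by conjugate Beta; sigma and the lam0s by log-scale random walk."""
    use_scr, use_occ, _ = _variant_flags(variant)
    new = state.copy()
    new.psi = float(
        rng.beta(priors.psi_a + new.N, priors.psi_b + new.M - new.N)
    )
    new.psi = min(max(new.psi, 1e-12), 1 - 1e-12)

    def mh_log_scale(attr, step):
        cur_lp = joint_log_posterior(new, bundle, variant, priors)
        prop = new.copy()
        val = getattr(new, attr)
        setattr(prop, attr, val * np.exp(step * rng.standard_normal()))
        prop_lp = joint_log_posterior(prop, bundle, variant, priors)
        ratio = prop_lp - cur_lp + np.log(getattr(prop, attr)) - np.log(val)
        if np.log(rng.uniform()) < ratio:
            setattr(new, attr, getattr(prop, attr))

    mh_log_scale("sigma", step_sigma)
    if use_scr:
        mh_log_scale("lam0_trap", step_lam0)
    if use_occ:
        mh_log_scale("lam0_cam", step_lam0)
    return new


def rj_update_covariate(
    state: AugmentedState,
    bundle: DataBundle,
    rng: np.random.Generator,
    priors: PriorConfig = PriorConfig(),
) -> AugmentedState:
    """Reversible-jump toggle of the bait effect beta1 on log(lam0_trap).

    Birth proposes beta1* ~ N(0, rj_proposal_sd); the acceptance ratio carries
    the exact prior/proposal correction. Prior inclusion probability is 0.5.
    """
    if bundle.traps.bait is None:
        raise ValueError("covariate selection requires a bait vector")
    new = state.copy()
    new.beta0 = np.log(max(new.lam0_trap, 1e-300))

    def scr_ll(st):
        return model_core.scr_loglik(st, bundle.traps, bundle.scr)

    if new.w == 0:
        b1 = priors.rj_proposal_sd * rng.standard_normal()
        trial = new.copy()
        trial.w, trial.beta1 = 1, float(b1)
        lr = (
            scr_ll(trial)
            - scr_ll(new)
            + stats.norm.logpdf(b1, 0, priors.beta_sd)
            - stats.norm.logpdf(b1, 0, priors.rj_proposal_sd)
        )
        if np.log(rng.uniform()) < lr:
            new = trial
    else:
        trial = new.copy()
        trial.w, trial.beta1 = 0, 0.0
        lr = (
            scr_ll(trial)
            - scr_ll(new)
            - stats.norm.logpdf(new.beta1, 0, priors.beta_sd)
            + stats.norm.logpdf(new.beta1, 0, priors.rj_proposal_sd)
        )
        if np.log(rng.uniform()) < lr:
            new = trial
    return new


# ---------------------------------------------------------------------------
# production fit


@dataclass
class ChainOutput:
    """Retained draws from all chains plus latent snapshots and diagnostics."""

    draws: dict  # param -> (n_chains, n_iter) array
    latent_z: np.ndarray  # (n_chains, n_snap, M)
    latent_s: np.ndarray  # (n_chains, n_snap, M, 2)
    accept_rates: np.ndarray  # (n_chains, 6)
    area: float
    variant: str
    n_obs: int
    M: int
    config: FitConfig
    latent_thin: int = 1

    @property
    def params(self) -> list:
        return list(self.draws.keys())

    def pooled(self, param: str) -> np.ndarray:
        return self.draws[param].ravel()

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format draws, one row per retained iteration."""
        n_chains, n_iter = next(iter(self.draws.values())).shape
        frames = []
        for c in range(n_chains):
            df = pd.DataFrame({k: v[c] for k, v in self.draws.items()})
            df.insert(0, "iteration", np.arange(n_iter))
            df.insert(0, "chain", c)
            frames.append(df)
        return pd.concat(frames, ignore_index=True)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, area: float, variant: str = "scr_occ_tel"):
        """Rebuild (draws only) from a frame written by :meth:`to_dataframe`."""
        chains = sorted(df["chain"].unique())
        params = [c for c in df.columns if c not in ("chain", "iteration")]
        draws = {
            p: np.stack([df.loc[df["chain"] == c, p].to_numpy() for c in chains])
            for p in params
        }
        return cls(
            draws=draws,
            latent_z=np.zeros((len(chains), 0, 0), dtype=np.int8),
            latent_s=np.zeros((len(chains), 0, 0, 2)),
            accept_rates=np.full((len(chains), 6), np.nan),
            area=area,
            variant=variant,
            n_obs=0,
            M=0,
            config=FitConfig(variant=variant if variant in _ALL_VARIANTS else "scr_occ_tel"),
        )


def _prepare_arrays(bundle: DataBundle, config: FitConfig):
    """Marshal the bundle into the flat arrays the kernel consumes."""
    use_scr, use_occ, use_tel = _variant_flags(config.variant)
    M = config.M
    if use_occ and (bundle.occ is None or bundle.cameras is None):
        raise ValueError(f"variant {config.variant!r} requires occupancy data")
    if use_tel and bundle.telemetry is None:
        raise ValueError(f"variant {config.variant!r} requires telemetry data")
    if config.variant == "tel":
        n_obs = bundle.telemetry.n_tagged
    else:
        n_obs = bundle.scr.n_individuals
    if M <= n_obs:
        raise ValueError("augmentation size M must exceed the number observed")

    Xt = np.ascontiguousarray(bundle.traps.coords, dtype=np.float64)
    Kt = bundle.traps.effort.astype(np.int64)
    keep = Kt > 0
    if not keep.all():
        logger.warning("dropping %d live traps with K_j = 0", int((~keep).sum()))
        Xt, Kt = Xt[keep], Kt[keep]
        yscr = bundle.scr.y[:, keep]
    else:
        yscr = bundle.scr.y
    yscr = np.ascontiguousarray(yscr, dtype=np.int64)
    bait = (
        bundle.traps.bait[keep].astype(np.int64)
        if bundle.traps.bait is not None
        else np.zeros(Kt.shape[0], dtype=np.int64)
    )

    if use_occ:
        Xc = np.ascontiguousarray(bundle.cameras.coords, dtype=np.float64)
        Kc = bundle.cameras.effort.astype(np.int64)
        yocc = bundle.occ.y.astype(np.int64)
        keepc = Kc > 0
        if not keepc.all():
            logger.warning("dropping %d cameras with K_j = 0", int((~keepc).sum()))
            Xc, Kc, yocc = Xc[keepc], Kc[keepc], yocc[keepc]
    else:
        Xc = np.zeros((0, 2))
        Kc = np.zeros(0, dtype=np.int64)
        yocc = np.zeros(0, dtype=np.int64)

    telR = np.zeros(M, dtype=np.int64)
    telC = np.zeros((M, 2))
    telSS = np.zeros(M)
    if use_tel:
        tel = bundle.telemetry
        slots = np.arange(tel.n_tagged) if config.variant == "tel" else tel.links
        cents = tel.centroids()
        ssqs = tel.sum_sq_dev()
        for k, slot in enumerate(slots):
            telR[slot] = tel.n_fixes[k]
            telC[slot] = cents[k]
            telSS[slot] = ssqs[k]

    if config.variant == "tel":
        yscr = np.zeros((n_obs, Kt.shape[0]), dtype=np.int64)

    return (yscr, Kt, Xt, bait, yocc, Kc, Xc, telR, telC, telSS, n_obs,
            int(use_scr), int(use_occ), int(use_tel))


def _init_state(bundle, config, n_obs, telR, telC, chain_rng):
    """Overdispersed per-chain initial values."""
    space = bundle.space
    M = config.M
    s0 = space.sample(M, chain_rng)
    if config.variant != "tel":
        y = bundle.scr.y
        coords = bundle.traps.coords
        for i in range(n_obs):
            wts = y[i].astype(float)
            c = (coords * wts[:, None]).sum(axis=0) / wts.sum()
            s0[i] = c + 0.1 * chain_rng.standard_normal(2)
    for i in range(M):
        if telR[i] > 0:
            s0[i] = telC[i] + 0.05 * chain_rng.standard_normal(2)
    s0[:, 0] = np.clip(s0[:, 0], space.xmin, space.xmax)
    s0[:, 1] = np.clip(s0[:, 1], space.ymin, space.ymax)
    z0 = np.zeros(M, dtype=np.int64)
    z0[:n_obs] = 1
    z0[n_obs:] = chain_rng.uniform(size=M - n_obs) < 0.3
    psi0 = float(np.clip(z0.mean() + 0.1 * chain_rng.uniform(-1, 1), 0.05, 0.95))
    sigma0 = config.sigma_init * float(np.exp(chain_rng.uniform(-0.7, 0.7)))
    sigma0 = min(sigma0, 0.9 * config.priors.sigma_max)
    lam0t0 = config.lam0_init * float(np.exp(chain_rng.uniform(-1.0, 1.0)))
    lam0c0 = config.lam0_init * float(np.exp(chain_rng.uniform(-1.0, 1.0)))
    lam0t0 = min(lam0t0, 0.5 * config.priors.lam0_max)
    lam0c0 = min(lam0c0, 0.5 * config.priors.lam0_max)
    return z0, s0, psi0, sigma0, lam0t0, lam0c0


def run_fit(bundle: DataBundle, config: FitConfig) -> ChainOutput:
    """Run seeded, independent chains of the Metropolis-within-Gibbs sampler.

    Systematic scan per iteration: z -> s -> (psi, sigma, lam0s, beta) -> RJ.
    Proposal-scale adaptation happens during burn-in only, so the retained
    kernel is a fixed (valid) MCMC kernel. Non-convergence is reported by the
    diagnostics in :func:`summarize`, never raised.
    """
    (yscr, Kt, Xt, bait, yocc, Kc, Xc, telR, telC, telSS, n_obs,
     use_scr, use_occ, use_tel) = _prepare_arrays(bundle, config)
    if config.covariate_selection and bundle.traps.bait is None:
        raise ValueError("covariate selection requires a bait vector on the live traps")
    cov_mode = _kernels.COV_RJ if config.covariate_selection else _kernels.COV_NONE
    pr = config.priors
    M = config.M
    area = bundle.space.area
    bounds = bundle.space.bounds

    latent_thin = config.latent_thin
    if latent_thin <= 0:
        latent_thin = max(1, config.n_iter // 400)

    ss = np.random.SeedSequence(config.seed)
    chain_seeds = ss.generate_state(2 * config.n_chains)

    per_chain = []
    for c in range(config.n_chains):
        chain_rng = np.random.default_rng(chain_seeds[2 * c])
        z0, s0, psi0, sigma0, lam0t0, lam0c0 = _init_state(
            bundle, config, n_obs, telR, telC, chain_rng
        )
        kernel_seed = int(chain_seeds[2 * c + 1] % np.iinfo(np.int32).max)
        out = _kernels.run_chain(
            yscr, Kt, Xt, bait, yocc, Kc, Xc, telR, telC, telSS,
            M, n_obs, bounds.astype(np.float64),
            use_scr, use_occ, use_tel, cov_mode,
            pr.sigma_max, pr.lam0_max, pr.beta_sd, pr.rj_proposal_sd,
            pr.psi_a, pr.psi_b,
            z0, s0.astype(np.float64), psi0, sigma0, lam0t0, lam0c0,
            float(np.log(max(lam0t0, 1e-300))), 0.0, 0,
            config.n_burn, config.n_iter, latent_thin, kernel_seed,
            config.step_s, config.step_sigma, config.step_lam0,
            config.step_lam0, config.step_beta, config.step_beta,
        )
        per_chain.append(out)

    cols = {"N": 0, "psi": 1, "sigma": 2}
    if use_scr:
        cols["lam0_trap"] = 3
    if use_occ:
        cols["lam0_cam"] = 4
    if cov_mode != _kernels.COV_NONE:
        cols.update(beta0=5, beta1=6, w=7)

    draws = {}
    for name, j in cols.items():
        draws[name] = np.stack([out[0][:, j] for out in per_chain])
    draws["D"] = draws["N"] / area
    # order: N, D first
    ordered = {"N": draws["N"], "D": draws["D"]}
    for k in cols:
        if k != "N":
            ordered[k] = draws[k]

    latent_z = np.stack([out[1] for out in per_chain])
    latent_s = np.stack([out[2] for out in per_chain])
    accept = np.stack([out[3] for out in per_chain])

    if config.n_iter > 0 and np.mean(draws["N"] >= M - 1) > 0.01:
        warnings.warn(
            "posterior mass of N touches the augmentation limit M; increase M",
            RuntimeWarning,
            stacklevel=2,
        )

    return ChainOutput(
        draws=ordered,
        latent_z=latent_z,
        latent_s=latent_s,
        accept_rates=accept,
        area=area,
        variant=config.variant,
        n_obs=n_obs,
        M=M,
        config=config,
        latent_thin=latent_thin,
    )


# ---------------------------------------------------------------------------
# summaries


def half_sample_mode(x: np.ndarray) -> float:
    """Robertson-Cryer half-sample mode: recursively narrow to the densest half."""
    x = np.sort(np.asarray(x, dtype=float).ravel())
    while x.size > 3:
        n = x.size
        h = (n + 1) // 2
        widths = x[h - 1:] - x[: n - h + 1]
        k = int(np.argmin(widths))
        x = x[k : k + h]
    if x.size == 3:
        return float(0.5 * (x[0] + x[1]) if x[1] - x[0] < x[2] - x[1] else 0.5 * (x[1] + x[2]))
    return float(x.mean())


def kde_mode(x: np.ndarray) -> float:
    """Gaussian-KDE mode (optional alternative point estimate)."""
    x = np.asarray(x, dtype=float).ravel()
    if np.ptp(x) == 0:
        return float(x[0])
    kde = stats.gaussian_kde(x)
    grid = np.linspace(x.min(), x.max(), 512)
    return float(grid[np.argmax(kde(grid))])


@dataclass
class PosteriorSummary:
    """Per-parameter posterior table with convergence diagnostics."""

    table: pd.DataFrame  # index: parameter; columns: mean mode sd q2.5 q97.5 cv rhat ess

    def __getitem__(self, param: str) -> pd.Series:
        return self.table.loc[param]

    def cv(self, param: str) -> float:
        return float(self.table.loc[param, "cv"])

    def mode(self, param: str) -> float:
        return float(self.table.loc[param, "mode"])

    @property
    def max_rhat(self) -> float:
        return float(np.nanmax(self.table["rhat"].to_numpy()))

    def __repr__(self) -> str:  # pragma: no cover
        return f"PosteriorSummary(\n{self.table.round(4)}\n)"


def _diagnostics(chain_draws: np.ndarray) -> tuple[float, float]:
    """Split-Rhat and bulk ESS (rank-normalized, Vehtari et al.) via ArviZ."""
    import arviz as az

    if np.ptp(chain_draws) == 0:
        return np.nan, np.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ds = az.convert_to_dataset(chain_draws)
        rhat = float(az.rhat(ds)["x"].values)
        ess = float(az.ess(ds)["x"].values)
    return rhat, ess


def summarize(
    chains: ChainOutput,
    area: Optional[float] = None,
    mode_estimator: str = "half_sample",
) -> PosteriorSummary:
    """Mean / mode / SD / 95% CRI / CV + split-Rhat and ESS per parameter.

    Point summaries pool all chains; diagnostics use the chain structure.
    ``N`` (realized) and ``D = N / area`` are included as derived parameters.
    """
    if not chains.draws or next(iter(chains.draws.values())).size == 0:
        raise ValueError("empty chains")
    if area is not None and area != chains.area:
        chains = ChainOutput(**{**chains.__dict__, "area": area})
        chains.draws["D"] = chains.draws["N"] / area
    mode_fn = half_sample_mode if mode_estimator == "half_sample" else kde_mode
    rows = {}
    for name, arr in chains.draws.items():
        pooled = arr.ravel()
        mean = float(pooled.mean())
        sd = float(pooled.std(ddof=1)) if pooled.size > 1 else 0.0
        q025, q975 = (np.quantile(pooled, [0.025, 0.975]) if pooled.size else (np.nan, np.nan))
        rhat, ess = _diagnostics(arr)
        rows[name] = {
            "mean": mean,
            "mode": mode_fn(pooled),
            "sd": sd,
            "q2.5": float(q025),
            "q97.5": float(q975),
            "cv": sd / mean if mean != 0 else np.nan,
            "rhat": rhat,
            "ess": ess,
        }
    return PosteriorSummary(table=pd.DataFrame(rows).T)


def cv_reduction(
    reference: PosteriorSummary, candidate: PosteriorSummary, param: str
) -> float:
    """Percent reduction in CV relative to ``reference``: 100 (CVr - CVc)/CVr."""
    cv_ref = reference.cv(param)
    cv_cand = candidate.cv(param)
    if cv_ref == 0:
        raise ValueError("reference CV is zero")
    return 100.0 * (cv_ref - cv_cand) / cv_ref
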