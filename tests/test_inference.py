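"""Sampler correctness: conjugacy, enumeration oracles, invariance, summaries."""

import warnings
from dataclasses import replace
from itertools import product

import numpy as np
import pytest
from scipy import stats
from scipy.special import expit

from scrim import (
    AugmentedState,
    DataBundle,
    FitConfig,
    OccData,
    PriorConfig,
    SCRData,
    StateSpace,
    TelemetryData,
    TrapArray,
    cv_reduction,
    run_fit,
    summarize,
)
from scrim import model_core as mc
from scrim.inference import (
    ChainOutput,
    half_sample_mode,
    joint_log_posterior,
    rj_update_covariate,
    update_params,
    update_s,
    update_z,
)
from scrim.types import CAMERA, LIVE_TRAP


@pytest.fixture
def toy():
    """2-detector, M=3 toy with one observed individual and fixed centers."""
    space = StateSpace(0, 4, 0, 4)
    traps = TrapArray(coords=[[1.0, 1.0], [2.0, 2.5]], kind=LIVE_TRAP, effort=[1, 1])
    cams = TrapArray(coords=[[3.0, 1.0], [1.5, 3.0]], kind=CAMERA, effort=[2, 1])
    scr = SCRData(y=[[1, 0]])
    occ = OccData(y=[1, 1])
    bundle = DataBundle(traps=traps, scr=scr, space=space, cameras=cams, occ=occ)
    state = AugmentedState(
        z=[1, 0, 0],
        s=[[1.2, 1.1], [2.8, 1.2], [1.6, 2.8]],
        psi=0.45,
        lam0_trap=0.5,
        lam0_cam=0.6,
        sigma=0.8,
        n_obs=1,
    )
    return bundle, state


def enumerate_z_posterior(bundle, state, variant="scr_occ"):
    """Posterior over latent z configurations with everything else fixed."""
    latent = range(state.n_obs, state.M)
    probs = {}
    for conf in product([0, 1], repeat=len(latent)):
        st = state.copy()
        st.z[state.n_obs:] = conf
        lp = mc.scr_loglik(st, bundle.traps, bundle.scr)
        if "occ" in variant:
            lp += mc.occ_loglik(st, bundle.cameras, bundle.occ)
        k = sum(conf)
        lp += k * np.log(state.psi) + (len(latent) - k) * np.log1p(-state.psi)
        probs[conf] = np.exp(lp)
    total = sum(probs.values())
    return {k: v / total for k, v in probs.items()}


class TestUpdateZ:
    def test_full_conditional_matches_enumeration_exactly(self, toy):
        bundle, state = toy
        post = enumerate_z_posterior(bundle, state)
        # conditional P(z_1 = 1 | z_2 = 0) from enumeration...
        p_enum = post[(1, 0)] / (post[(1, 0)] + post[(0, 0)])
        # ...vs the sampler's closed-form conditional
        from scrim.inference import _latent_zero_loglik

        st = state.copy()
        st.z[2] = 0
        delta = _latent_zero_loglik(st, bundle, 1, True, True)
        p_formula = expit(np.log(state.psi) - np.log1p(-state.psi) + delta)
        assert p_formula == pytest.approx(p_enum, abs=1e-10)

    def test_far_individual_conditional_is_psi(self, toy):
        bundle, state = toy
        st = state.copy()
        st.s[1] = [3.9, 3.9]
        st.sigma = 0.05  # far from every detector at this scale
        rng = np.random.default_rng(0)
        draws = [update_z(st, bundle, rng, "scr_occ").z[1] for _ in range(4000)]
        assert np.mean(draws) == pytest.approx(st.psi, abs=0.03)

    def test_zero_rates_conditional_is_psi(self, toy):
        bundle, state = toy
        b0 = DataBundle(
            traps=bundle.traps, scr=bundle.scr, space=bundle.space,
            cameras=bundle.cameras, occ=OccData(y=[0, 0]),
        )
        st = state.copy()
        st.lam0_trap = 0.0
        st.lam0_cam = 0.0
        rng = np.random.default_rng(1)
        draws = np.array([update_z(st, b0, rng, "scr_occ").z[1:] for _ in range(4000)])
        assert draws.mean() == pytest.approx(st.psi, abs=0.03)

    def test_gibbs_marginal_matches_enumeration(self, toy):
        bundle, state = toy
        post = enumerate_z_posterior(bundle, state)
        target = np.zeros(3)
        for (z2, z3), p in post.items():
            target[z2 + z3] += p
        rng = np.random.default_rng(2)
        st = state.copy()
        counts = np.zeros(3)
        for _ in range(30000):
            st = update_z(st, bundle, rng, "scr_occ")
            counts[st.z[1] + st.z[2]] += 1
        tv = 0.5 * np.abs(counts / counts.sum() - target).sum()
        assert tv < 0.02


class TestUpdateS:
    def test_prior_refresh_when_excluded(self, toy):
        bundle, state = toy
        st = state.copy()
        st.z[1:] = 0
        rng = np.random.default_rng(3)
        pts = np.array([update_s(st, bundle, rng, "scr").s[1] for _ in range(3000)])
        # marginally uniform on S: mean at center, SD of uniform
        np.testing.assert_allclose(pts.mean(axis=0), [2.0, 2.0], atol=0.1)
        np.testing.assert_allclose(pts.std(axis=0), 4 / np.sqrt(12), atol=0.1)

    def test_telemetry_conjugate_posterior(self):
        # a single telemetry-only individual: s | fixes ~ N(centroid, sigma^2/R)
        space = StateSpace(-5, 5, -5, 5)
        traps = TrapArray(coords=[[0.0, 0.0]], kind=LIVE_TRAP, effort=[1])
        scr = SCRData(y=[[1]])
        rng = np.random.default_rng(4)
        sigma = 0.8
        fixes = rng.normal([1.0, -0.5], sigma, size=(25, 2))
        tel = TelemetryData(fixes=[fixes], links=[0])
        bundle = DataBundle(traps=traps, scr=scr, space=space, telemetry=tel)
        st = AugmentedState(
            z=[1], s=[[0.0, 0.0]], psi=0.5, lam0_trap=1e-9, lam0_cam=0.1,
            sigma=sigma, n_obs=1,
        )
        samples = []
        for it in range(6000):
            st = update_s(st, bundle, rng, "tel", step=0.3)
            if it > 500:
                samples.append(st.s[0].copy())
        samples = np.array(samples)
        np.testing.assert_allclose(samples.mean(axis=0), fixes.mean(axis=0), atol=0.05)
        np.testing.assert_allclose(samples.std(axis=0), sigma / np.sqrt(25), rtol=0.25)


class TestUpdateParams:
    def test_psi_conjugacy(self, toy):
        bundle, state = toy
        st = state.copy()
        st.z = np.array([1] * 1 + [1] * 56 + [0] * 143)
        st.s = np.vstack([st.s, bundle.space.sample(197, np.random.default_rng(5))])
        st = AugmentedState(
            z=st.z, s=st.s, psi=0.3, lam0_trap=0.0, lam0_cam=0.0, sigma=0.8, n_obs=1
        )
        # with sum z = 57 and M = 200: psi | z ~ Beta(58, 144)
        rng = np.random.default_rng(6)
        draws = np.array(
            [update_params(st, bundle, rng, "scr").psi for _ in range(4000)]
        )
        a, b = 1 + 57, 1 + 200 - 57
        assert draws.mean() == pytest.approx(a / (a + b), abs=0.005)
        assert draws.std() == pytest.approx(stats.beta(a, b).std(), rel=0.1)

    def test_sigma_concentrates_at_telemetry_profile(self):
        # handled end-to-end in acceptance criterion 2; here: joint_log_posterior
        # is maximized in sigma near the closed-form profile value
        rng = np.random.default_rng(7)
        space = StateSpace(-5, 5, -5, 5)
        traps = TrapArray(coords=[[0.0, 0.0]], kind=LIVE_TRAP, effort=[1])
        fixes = rng.normal(0.0, 0.7, size=(200, 2))
        tel = TelemetryData(fixes=[fixes], links=[0])
        bundle = DataBundle(
            traps=traps, scr=SCRData(y=[[1]]), space=space, telemetry=tel
        )
        from scrim.model_core import telemetry_sigma_profile_mle

        prof = telemetry_sigma_profile_mle(tel)
        sigmas = np.linspace(0.5, 1.0, 2001)

        def lp(sig):
            st = AugmentedState(
                z=[1], s=[fixes.mean(axis=0)], psi=0.5, lam0_trap=0.1, lam0_cam=0.1,
                sigma=sig, n_obs=1,
            )
            return mc.telemetry_loglik(st, bundle.telemetry)

        best = sigmas[np.argmax([lp(s) for s in sigmas])]
        assert best == pytest.approx(prof, abs=1e-3)


class TestJointLogPosterior:
    def test_scr_variant_additivity(self, toy):
        bundle, state = toy
        pr = PriorConfig()
        got = joint_log_posterior(state, bundle, "scr", pr)
        expected = (
            mc.scr_loglik(state, bundle.traps, bundle.scr)
            + state.N * np.log(state.psi)
            + (state.M - state.N) * np.log1p(-state.psi)
            + stats.beta.logpdf(state.psi, 1, 1)
        )
        assert got == pytest.approx(expected, abs=1e-10)

    def test_vanishing_occ_term(self, toy):
        bundle, state = toy
        b0 = DataBundle(
            traps=bundle.traps, scr=bundle.scr, space=bundle.space,
            cameras=bundle.cameras, occ=OccData(y=[0, 0]),
        )
        st = state.copy()
        st.lam0_cam = 0.0
        assert joint_log_posterior(st, b0, "scr_occ") == pytest.approx(
            joint_log_posterior(st, b0, "scr"), abs=1e-10
        )

    def test_finite_on_simulated_data(self, sim_bundle):
        bundle, _ = sim_bundle
        rng = np.random.default_rng(8)
        n = bundle.scr.n_individuals
        for _ in range(25):
            # admissible fuzz: every individual included, sigma bounded away
            # from 0 so no camera with detections has likelihood-zero rate
            M = 50
            st = AugmentedState(
                z=np.ones(M, dtype=int),
                s=bundle.space.sample(M, rng),
                psi=rng.uniform(0.05, 0.95),
                lam0_trap=rng.uniform(0.01, 0.9),
                lam0_cam=rng.uniform(0.01, 0.9),
                sigma=rng.uniform(0.4, 4.9),
                n_obs=n,
            )
            lp = joint_log_posterior(st, bundle, "scr_occ_tel")
            assert np.isfinite(lp)

    def test_missing_block_rejected(self, toy):
        bundle, state = toy
        b = DataBundle(traps=bundle.traps, scr=bundle.scr, space=bundle.space)
        with pytest.raises(ValueError):
            joint_log_posterior(state, b, "scr_occ")


class TestGewekeInvariance:
    """Successive-conditional simulation: alternating data simulation and the
    update blocks must leave the prior-predictive distribution invariant."""

    def test_toy_successive_conditional(self):
        rng = np.random.default_rng(9)
        space = StateSpace(0, 3, 0, 3)
        traps = TrapArray(coords=[[1.0, 1.5], [2.0, 1.5]], kind=LIVE_TRAP, effort=[2, 2])
        pr = PriorConfig(sigma_max=2.0, lam0_max=1.0)
        M = 3
        sweeps = 22000  # sigma's autocorrelation time is ~50 sweeps here
        sigmas, lams, psis, nz = [], [], [], []
        # start from the prior
        psi = rng.beta(1, 1)
        sigma = rng.uniform(0, pr.sigma_max)
        lam0 = rng.uniform(0, pr.lam0_max)
        z = (rng.random(M) < psi).astype(int)
        s = space.sample(M, rng)
        for _ in range(sweeps):
            # data | state; then permute slots so captured rows sit first
            # (the sampler's layout contract), which is measure-preserving
            p = -np.expm1(-mc.trap_rates(s, traps.coords, lam0, sigma))
            y = rng.binomial(traps.effort[None, :], p * z[:, None])
            captured = y.sum(axis=1) > 0
            order = np.argsort(~captured, kind="stable")
            y, z, s = y[order], z[order], s[order]
            n = int(captured.sum())
            data = SCRData.__new__(SCRData)
            data.y = y[:n]
            data.individual_ids = [str(i) for i in range(n)]
            bundle = DataBundle.__new__(DataBundle)
            bundle.traps, bundle.scr, bundle.space = traps, data, space
            bundle.cameras = bundle.occ = bundle.telemetry = None
            state = AugmentedState(
                z=z, s=s, psi=psi, lam0_trap=lam0, lam0_cam=0.1, sigma=sigma, n_obs=n
            )
            state = update_z(state, bundle, rng, "scr")
            state = update_s(state, bundle, rng, "scr", step=0.8)
            state = update_params(state, bundle, rng, "scr", pr, 0.4, 0.6)
            z, s, psi, sigma, lam0 = state.z, state.s, state.psi, state.sigma, state.lam0_trap
            sigmas.append(sigma)
            lams.append(lam0)
            psis.append(psi)
            nz.append(z.sum())
        # marginals must match the priors: U(0,2), U(0,1), Beta(1,1)
        thin = slice(1000, None, 30)
        for vals, dist in [
            (np.array(sigmas)[thin], stats.uniform(0, 2)),
            (np.array(lams)[thin], stats.uniform(0, 1)),
            (np.array(psis)[thin], stats.uniform(0, 1)),
        ]:
            ks = stats.ks_1samp(vals, dist.cdf)
            assert ks.pvalue > 0.005, (dist, ks)
        assert np.mean(nz) == pytest.approx(1.5, abs=0.15)  # E[M psi] = 1.5


class TestRunFit:
    def test_zero_iterations_no_crash(self, sim_bundle):
        bundle, _ = sim_bundle
        cfg = FitConfig(n_chains=1, n_iter=0, n_burn=5, seed=0, M=60)
        out = run_fit(bundle, cfg)
        assert out.draws["N"].shape == (1, 0)

    def test_seed_determinism(self, sim_bundle):
        bundle, _ = sim_bundle
        cfg = FitConfig(n_chains=2, n_iter=120, n_burn=60, seed=42, M=80)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = run_fit(bundle, cfg)
            b = run_fit(bundle, cfg)
        for k in a.draws:
            np.testing.assert_array_equal(a.draws[k], b.draws[k])
        c = run_fit(bundle, replace(cfg, seed=43))
        assert not np.array_equal(a.draws["sigma"], c.draws["sigma"])

    def test_draw_count_contract(self, fitted_chains):
        cfg, chains = fitted_chains
        for arr in chains.draws.values():
            assert arr.shape == (cfg.n_chains, cfg.n_iter)

    def test_acceptance_rates_reasonable(self, fitted_chains):
        _, chains = fitted_chains
        # adapted blocks: s, sigma, lam0_trap, lam0_cam
        rates = chains.accept_rates[:, :4]
        assert np.all(rates > 0.1) and np.all(rates < 0.6)

    def test_variant_typo_rejected(self):
        with pytest.raises(ValueError, match="valid"):
            FitConfig(variant="scr-occ")

    def test_missing_data_block_rejected(self, sim_bundle):
        bundle, _ = sim_bundle
        b = DataBundle(traps=bundle.traps, scr=bundle.scr, space=bundle.space)
        with pytest.raises(ValueError):
            run_fit(b, FitConfig(variant="scr_occ", n_iter=10, n_burn=0, M=50))

    def test_dataframe_round_trip(self, fitted_chains):
        _, chains = fitted_chains
        df = chains.to_dataframe()
        assert len(df) == chains.config.n_chains * chains.config.n_iter
        back = ChainOutput.from_dataframe(df, area=chains.area, variant=chains.variant)
        np.testing.assert_allclose(back.draws["D"], chains.draws["D"])


class TestRJ:
    def _bait_bundle(self, beta0, beta1, seed=0, J=40, K=25, n_pop=60):
        """Simulate live-trap data with a true bait effect on log lam0."""
        rng = np.random.default_rng(seed)
        space = StateSpace(0, 10, 0, 10)
        coords = rng.uniform(1, 9, (J, 2))
        bait = (np.arange(J) % 2).astype(int)
        traps = TrapArray(coords=coords, kind=LIVE_TRAP, effort=np.full(J, K), bait=bait)
        s = space.sample(n_pop, rng)
        lam0j = np.exp(beta0 + beta1 * bait)
        d2 = ((s[:, None, :] - coords[None, :, :]) ** 2).sum(-1)
        p = -np.expm1(-lam0j[None, :] * np.exp(-d2 / (2 * 0.8**2)))
        y = rng.binomial(K, p)
        y = y[y.sum(axis=1) > 0]
        return DataBundle(traps=traps, scr=SCRData(y=y), space=space)

    def test_strong_effect_selected(self):
        bundle = self._bait_bundle(beta0=np.log(0.03), beta1=2.0, seed=1)
        cfg = FitConfig(
            variant="scr", covariate_selection=True, n_chains=2, n_iter=1500,
            n_burn=600, seed=5, M=120, sigma_init=0.8, lam0_init=0.05,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            chains = run_fit(bundle, cfg)
        assert chains.draws["w"].mean() > 0.9

    def test_null_effect_rarely_selected(self):
        bundle = self._bait_bundle(beta0=np.log(0.03), beta1=0.0, seed=2)
        cfg = FitConfig(
            variant="scr", covariate_selection=True, n_chains=2, n_iter=1500,
            n_burn=600, seed=6, M=120, sigma_init=0.8, lam0_init=0.05,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            chains = run_fit(bundle, cfg)
        assert chains.draws["w"].mean() < 0.4

    def test_flag_without_bait_rejected(self, sim_bundle):
        bundle, _ = sim_bundle
        cfg = FitConfig(covariate_selection=True, n_iter=10, n_burn=0, M=50)
        with pytest.raises(ValueError, match="bait"):
            run_fit(bundle, cfg)

    def test_reference_rj_reversibility(self, toy):
        bundle, state = toy
        bundle.traps.bait = np.array([0, 1])
        rng = np.random.default_rng(10)
        st = state.copy()
        ws = []
        for _ in range(2000):
            st = rj_update_covariate(st, bundle, rng)
            ws.append(st.w)
        assert 0.0 < np.mean(ws) < 1.0  # moves in both directions


class TestSummaries:
    def test_cv_matches_reported_convention(self, rng):
        # CV = posterior SD / posterior mean; e.g. mean .370, SD .081 -> .219
        x = rng.standard_normal(20000)
        x = (x - x.mean()) / x.std(ddof=1) * 0.081 + 0.370
        draws = {"D": x.reshape(2, -1), "N": x.reshape(2, -1) * 100}
        chains = ChainOutput(
            draws=draws, latent_z=np.zeros((2, 0, 0), dtype=np.int8),
            latent_s=np.zeros((2, 0, 0, 2)), accept_rates=np.zeros((2, 6)),
            area=100.0, variant="scr", n_obs=0, M=0, config=FitConfig(),
        )
        summ = summarize(chains)
        assert summ.cv("D") == pytest.approx(0.219, abs=0.001)

    def test_constant_chain_flags(self):
        draws = {"D": np.full((2, 50), 1.3), "N": np.full((2, 50), 13.0)}
        chains = ChainOutput(
            draws=draws, latent_z=np.zeros((2, 0, 0), dtype=np.int8),
            latent_s=np.zeros((2, 0, 0, 2)), accept_rates=np.zeros((2, 6)),
            area=10.0, variant="scr", n_obs=0, M=0, config=FitConfig(),
        )
        summ = summarize(chains)
        assert summ["D"]["sd"] == pytest.approx(0.0, abs=1e-12)
        assert summ.cv("D") == pytest.approx(0.0, abs=1e-12)
        assert np.isnan(summ["D"]["rhat"])

    def test_mode_of_symmetric_sample_near_mean(self, rng):
        # the half-sample mode converges slowly (~n^{-1/3}); average replicates
        modes = [half_sample_mode(rng.normal(5.0, 1.0, size=20000)) for _ in range(8)]
        assert np.mean(modes) == pytest.approx(5.0, abs=0.1)

    def test_empty_chains_rejected(self):
        chains = ChainOutput(
            draws={}, latent_z=np.zeros((1, 0, 0), dtype=np.int8),
            latent_s=np.zeros((1, 0, 0, 2)), accept_rates=np.zeros((1, 6)),
            area=1.0, variant="scr", n_obs=0, M=0, config=FitConfig(),
        )
        with pytest.raises(ValueError):
            summarize(chains)

    def test_quantile_ordering(self, fitted_chains):
        _, chains = fitted_chains
        summ = summarize(chains)
        t = summ.table
        assert (t["q2.5"] <= t["q97.5"]).all()
        assert (t["cv"].dropna() >= 0).all()


class TestCvReduction:
    def _summary(self, cv):
        import pandas as pd

        return type(summarize.__annotations__.get("return", object), (), {})() if False else (
            __import__("scrim.inference", fromlist=["PosteriorSummary"]).PosteriorSummary(
                table=pd.DataFrame({"cv": {"D": cv}})
            )
        )

    def test_reported_value(self):
        ref, cand = self._summary(0.349), self._summary(0.219)
        assert 37.0 <= cv_reduction(ref, cand, "D") <= 37.3

    def test_identity_zero(self):
        ref = self._summary(0.25)
        assert cv_reduction(ref, ref, "D") == 0.0

    def test_worse_candidate_negative(self):
        assert cv_reduction(self._summary(0.2), self._summary(0.3), "D") < 0

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            cv_reduction(self._summary(0.0), self._summary(0.1), "D")
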