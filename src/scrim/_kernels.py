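"""Numba kernels for the Metropolis-within-Gibbs sampler.

These are the production counterparts of :mod:`scrim.model_core`; they drop
additive constants that cancel in Metropolis ratios (binomial coefficients in
the occupancy term, the 2*pi telemetry constant) and zero out encounter rates
beyond ``_CUTOFF * sigma^2`` squared distance (rate factor < 2e-11) for
*unobserved* contributions. Equivalence with the reference implementation is
asserted in the test suite via log-likelihood differences.

Layout conventions: the first ``n_obs`` augmented slots are the observed
individuals (z pinned to 1); telemetry is carried as per-slot sufficient
statistics (fix count, fix centroid, summed squared deviation).
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

_CUTOFF = 50.0  # in units of sigma^2

# covariate modes
COV_NONE = 0
COV_FIXED = 1
COV_RJ = 2


@njit(cache=True)
def seed_kernel_rng(seed):
    np.random.seed(seed)


@njit(cache=True)
def _lchoose(K, y):
    return math.lgamma(K + 1.0) - math.lgamma(y + 1.0) - math.lgamma(K - y + 1.0)


@njit(cache=True)
def _rate_row(sx, sy, X, lam0j, sigma, out):
    """Encounter-rate row lambda_j; zero beyond the distance cutoff."""
    inv2s2 = 1.0 / (2.0 * sigma * sigma)
    cut = _CUTOFF * sigma * sigma
    for j in range(X.shape[0]):
        dx = sx - X[j, 0]
        dy = sy - X[j, 1]
        d2 = dx * dx + dy * dy
        out[j] = 0.0 if d2 > cut else lam0j[j] * math.exp(-d2 * inv2s2)


@njit(cache=True)
def _zero_mass_row(sx, sy, X, K, lam0j, sigma):
    """log P(all-zero binomial history) = -sum_j K_j lambda_j."""
    inv2s2 = 1.0 / (2.0 * sigma * sigma)
    cut = _CUTOFF * sigma * sigma
    acc = 0.0
    for j in range(X.shape[0]):
        dx = sx - X[j, 0]
        dy = sy - X[j, 1]
        d2 = dx * dx + dy * dy
        if d2 <= cut:
            acc += K[j] * lam0j[j] * math.exp(-d2 * inv2s2)
    return -acc


@njit(cache=True)
def _scr_obs_row_ll(sx, sy, X, K, yrow, lam0j, sigma):
    """Exact binomial log-likelihood of one observed individual's count row."""
    inv2s2 = 1.0 / (2.0 * sigma * sigma)
    cut = _CUTOFF * sigma * sigma
    ll = 0.0
    for j in range(X.shape[0]):
        dx = sx - X[j, 0]
        dy = sy - X[j, 1]
        d2 = dx * dx + dy * dy
        y = yrow[j]
        if y == 0:
            if d2 <= cut:
                ll -= K[j] * lam0j[j] * math.exp(-d2 * inv2s2)
        else:
            lam = lam0j[j] * math.exp(-d2 * inv2s2)
            p = -math.expm1(-lam)
            if p <= 0.0:
                return -1.0e300
            ll += _lchoose(K[j], y) + y * math.log(p) - (K[j] - y) * lam
    return ll


@njit(cache=True)
def _occ_term(t, y, K):
    """Per-camera binomial log-mass (no lchoose) with total rate t."""
    if y == 0:
        return -K * t
    if t <= 0.0:
        return -1.0e300
    q = -math.expm1(-t)
    return y * math.log(q) - (K - y) * t


@njit(cache=True)
def _occ_total(z, s, Xc, Kc, yocc, lam0c, sigma, t_out):
    """Occupancy log-likelihood from scratch; fills per-camera total rates."""
    Jc = Xc.shape[0]
    for j in range(Jc):
        t_out[j] = 0.0
    inv2s2 = 1.0 / (2.0 * sigma * sigma)
    cut = _CUTOFF * sigma * sigma
    for i in range(z.shape[0]):
        if z[i] == 1:
            for j in range(Jc):
                dx = s[i, 0] - Xc[j, 0]
                dy = s[i, 1] - Xc[j, 1]
                d2 = dx * dx + dy * dy
                if d2 <= cut:
                    t_out[j] += lam0c * math.exp(-d2 * inv2s2)
    ll = 0.0
    for j in range(Jc):
        ll += _occ_term(t_out[j], yocc[j], Kc[j])
    return ll


@njit(cache=True)
def _scr_total(z, s, n_obs, Xt, Kt, y, lam0j, sigma):
    ll = 0.0
    for i in range(n_obs):
        ll += _scr_obs_row_ll(s[i, 0], s[i, 1], Xt, Kt, y[i], lam0j, sigma)
    for i in range(n_obs, z.shape[0]):
        if z[i] == 1:
            ll += _zero_mass_row(s[i, 0], s[i, 1], Xt, Kt, lam0j, sigma)
    return ll


@njit(cache=True)
def _tel_total(s, telR, telC, telSS, sigma):
    """Telemetry log-likelihood up to the -R log(2 pi) constant."""
    inv2s2 = 1.0 / (2.0 * sigma * sigma)
    ll = 0.0
    for i in range(telR.shape[0]):
        R = telR[i]
        if R > 0:
            dx = telC[i, 0] - s[i, 0]
            dy = telC[i, 1] - s[i, 1]
            ll += -2.0 * R * math.log(sigma) - (telSS[i] + R * (dx * dx + dy * dy)) * inv2s2
    return ll


@njit(cache=True)
def _update_z(z, s, n_obs, Xt, Kt, Xc, Kc, yocc, lam0j, lam0c, sigma, psi,
              t, use_scr, use_occ, a_buf):
    """Gibbs scan over the latent inclusion indicators; keeps t in sync."""
    log_odds_psi = math.log(psi) - math.log1p(-psi)
    Jc = Xc.shape[0]
    for i in range(n_obs, z.shape[0]):
        logit = log_odds_psi
        if use_scr:
            logit += _zero_mass_row(s[i, 0], s[i, 1], Xt, Kt, lam0j, sigma)
        if use_occ:
            inv2s2 = 1.0 / (2.0 * sigma * sigma)
            cut = _CUTOFF * sigma * sigma
            for j in range(Jc):
                dx = s[i, 0] - Xc[j, 0]
                dy = s[i, 1] - Xc[j, 1]
                d2 = dx * dx + dy * dy
                a_buf[j] = 0.0 if d2 > cut else lam0c * math.exp(-d2 * inv2s2)
            if z[i] == 1:  # remove own contribution first
                for j in range(Jc):
                    if a_buf[j] > 0.0:
                        t[j] -= a_buf[j]
                        if t[j] < 0.0:
                            t[j] = 0.0
            for j in range(Jc):
                if a_buf[j] > 0.0:
                    logit += _occ_term(t[j] + a_buf[j], yocc[j], Kc[j]) - _occ_term(
                        t[j], yocc[j], Kc[j]
                    )
        if logit > 35.0:
            p1 = 1.0
        elif logit < -35.0:
            p1 = 0.0
        else:
            p1 = 1.0 / (1.0 + math.exp(-logit))
        znew = 1 if np.random.rand() < p1 else 0
        z[i] = znew
        if use_occ and znew == 1:
            for j in range(Jc):
                if a_buf[j] > 0.0:
                    t[j] += a_buf[j]


@njit(cache=True)
def _update_s(z, s, n_obs, Xt, Kt, yscr, Xc, Kc, yocc, lam0j, lam0c, sigma,
              telR, telC, telSS, bounds, steps, t, use_scr, use_occ, use_tel,
              a_old, a_new, acc_i, att_i):
    """Per-individual random-walk update of activity centers.

    ``steps`` holds one proposal scale per individual (telemetered animals
    need far smaller steps than diffuse latent ones). Unobserved slots with
    z = 0 are refreshed from the uniform prior (their full conditional).
    Returns (accepted, attempted) Metropolis counts; per-individual counts
    accumulate into ``acc_i`` / ``att_i``.
    """
    xmin, xmax, ymin, ymax = bounds[0], bounds[1], bounds[2], bounds[3]
    Jc = Xc.shape[0]
    inv2s2 = 1.0 / (2.0 * sigma * sigma)
    cut = _CUTOFF * sigma * sigma
    acc = 0
    att = 0
    for i in range(z.shape[0]):
        if i >= n_obs and z[i] == 0:
            s[i, 0] = xmin + (xmax - xmin) * np.random.rand()
            s[i, 1] = ymin + (ymax - ymin) * np.random.rand()
            continue
        att += 1
        att_i[i] += 1
        px = s[i, 0] + steps[i] * np.random.randn()
        py = s[i, 1] + steps[i] * np.random.randn()
        if px < xmin or px > xmax or py < ymin or py > ymax:
            continue
        dll = 0.0
        if use_scr:
            if i < n_obs:
                dll += _scr_obs_row_ll(px, py, Xt, Kt, yscr[i], lam0j, sigma)
                dll -= _scr_obs_row_ll(s[i, 0], s[i, 1], Xt, Kt, yscr[i], lam0j, sigma)
            else:
                dll += _zero_mass_row(px, py, Xt, Kt, lam0j, sigma)
                dll -= _zero_mass_row(s[i, 0], s[i, 1], Xt, Kt, lam0j, sigma)
        if use_occ:
            for j in range(Jc):
                dx = s[i, 0] - Xc[j, 0]
                dy = s[i, 1] - Xc[j, 1]
                d2 = dx * dx + dy * dy
                a_old[j] = 0.0 if d2 > cut else lam0c * math.exp(-d2 * inv2s2)
                dx = px - Xc[j, 0]
                dy = py - Xc[j, 1]
                d2 = dx * dx + dy * dy
                a_new[j] = 0.0 if d2 > cut else lam0c * math.exp(-d2 * inv2s2)
                if a_old[j] > 0.0 or a_new[j] > 0.0:
                    base = t[j] - a_old[j]
                    if base < 0.0:
                        base = 0.0
                    dll += _occ_term(base + a_new[j], yocc[j], Kc[j]) - _occ_term(
                        base + a_old[j], yocc[j], Kc[j]
                    )
        if use_tel and telR[i] > 0:
            R = telR[i]
            dxn = telC[i, 0] - px
            dyn = telC[i, 1] - py
            dxo = telC[i, 0] - s[i, 0]
            dyo = telC[i, 1] - s[i, 1]
            dll -= R * (dxn * dxn + dyn * dyn - dxo * dxo - dyo * dyo) * inv2s2
        if dll >= 0.0 or math.log(np.random.rand()) < dll:
            acc += 1
            acc_i[i] += 1
            s[i, 0] = px
            s[i, 1] = py
            if use_occ:
                for j in range(Jc):
                    if a_old[j] > 0.0 or a_new[j] > 0.0:
                        t[j] += a_new[j] - a_old[j]
                        if t[j] < 0.0:
                            t[j] = 0.0
    return acc, att


@njit(cache=True)
def _lam0j_fill(out, cov_mode, w, beta0, beta1, bait, lam0t):
    if cov_mode == COV_NONE:
        for j in range(out.shape[0]):
            out[j] = lam0t
    else:
        for j in range(out.shape[0]):
            if w == 1:
                out[j] = math.exp(beta0 + beta1 * bait[j])
            else:
                out[j] = math.exp(beta0)


@njit(cache=True)
def run_chain(
    # data
    yscr, Kt, Xt, bait, yocc, Kc, Xc, telR, telC, telSS,
    # structure
    M, n_obs, bounds, use_scr, use_occ, use_tel, cov_mode,
    # priors
    sigma_max, lam0_max, beta_sd, rj_prop_sd, psi_a, psi_b,
    # init
    z0, s0, psi0, sigma0, lam0t0, lam0c0, beta0_0, beta1_0, w0,
    # run control
    n_burn, n_keep, latent_thin, seed,
    # proposal scales (initial)
    step_s0, step_sigma0, step_lam0t0, step_lam0c0, step_beta0_0, step_beta1_0,
):
    """One MCMC chain. Returns (draws, latent_z, latent_s, accept_rates, steps).

    draws columns: N, psi, sigma, lam0_trap, lam0_cam, beta0, beta1, w.
    Adaptation (Robbins-Monro toward 0.35 acceptance) runs during burn-in only.
    """
    np.random.seed(seed)
    Jt = Xt.shape[0]
    Jc = Xc.shape[0]

    z = z0.copy()
    s = s0.copy()
    psi = psi0
    sigma = sigma0
    lam0t = lam0t0
    lam0c = lam0c0
    beta0 = beta0_0
    beta1 = beta1_0
    w = w0

    lam0j = np.empty(Jt)
    _lam0j_fill(lam0j, cov_mode, w, beta0, beta1, bait, lam0t)
    lamj_prop = np.empty(Jt)

    t = np.zeros(Jc)
    a_buf = np.zeros(Jc)
    a_old = np.zeros(Jc)
    a_new = np.zeros(Jc)
    occ_ll = _occ_total(z, s, Xc, Kc, yocc, lam0c, sigma, t) if use_occ else 0.0

    steps_s = np.full(M, step_s0)
    acc_s_i = np.zeros(M)
    att_s_i = np.zeros(M)
    step_sigma = step_sigma0
    step_lam0t = step_lam0t0
    step_lam0c = step_lam0c0
    step_beta0 = step_beta0_0
    step_beta1 = step_beta1_0

    n_total = n_burn + n_keep
    draws = np.empty((n_keep, 8))
    n_snap = 0 if latent_thin <= 0 else (n_keep + latent_thin - 1) // latent_thin
    latent_z = np.zeros((n_snap, M), dtype=np.int8)
    latent_s = np.zeros((n_snap, M, 2))
    snap = 0

    # acceptance bookkeeping: s, sigma, lam0t(or beta0), lam0c, beta1, rj
    acc = np.zeros(6)
    att = np.zeros(6)
    win_acc = np.zeros(6)
    win_att = np.zeros(6)
    adapt_n = 0

    for it in range(n_total):
        # ---- z | rest (Gibbs) ----
        _update_z(z, s, n_obs, Xt, Kt, Xc, Kc, yocc, lam0j, lam0c, sigma, psi,
                  t, use_scr, use_occ, a_buf)

        # ---- s | rest (per-individual Metropolis / prior refresh) ----
        a, b = _update_s(z, s, n_obs, Xt, Kt, yscr, Xc, Kc, yocc, lam0j, lam0c,
                         sigma, telR, telC, telSS, bounds, steps_s, t,
                         use_scr, use_occ, use_tel, a_old, a_new, acc_s_i, att_s_i)
        acc[0] += a
        att[0] += b
        win_acc[0] += a
        win_att[0] += b

        # ---- psi | z (conjugate Beta) ----
        Nz = 0
        for i in range(M):
            Nz += z[i]
        psi = np.random.beta(psi_a + Nz, psi_b + M - Nz)
        if psi < 1e-12:
            psi = 1e-12
        if psi > 1.0 - 1e-12:
            psi = 1.0 - 1e-12

        # current likelihood parts for the parameter block
        cur_scr = _scr_total(z, s, n_obs, Xt, Kt, yscr, lam0j, sigma) if use_scr else 0.0
        cur_occ = _occ_total(z, s, Xc, Kc, yocc, lam0c, sigma, t) if use_occ else 0.0
        cur_tel = _tel_total(s, telR, telC, telSS, sigma) if use_tel else 0.0

        # ---- sigma (log random walk, U(0, sigma_max) prior) ----
        att[1] += 1
        win_att[1] += 1
        sig_p = sigma * math.exp(step_sigma * np.random.randn())
        if 0.0 < sig_p < sigma_max:
            new_scr = _scr_total(z, s, n_obs, Xt, Kt, yscr, lam0j, sig_p) if use_scr else 0.0
            new_occ = _occ_total(z, s, Xc, Kc, yocc, lam0c, sig_p, a_buf) if use_occ else 0.0
            new_tel = _tel_total(s, telR, telC, telSS, sig_p) if use_tel else 0.0
            dll = (new_scr + new_occ + new_tel) - (cur_scr + cur_occ + cur_tel)
            dll += math.log(sig_p) - math.log(sigma)  # log-RW Jacobian
            if dll >= 0.0 or math.log(np.random.rand()) < dll:
                sigma = sig_p
                cur_scr = new_scr
                cur_occ = new_occ
                cur_tel = new_tel
                acc[1] += 1
                win_acc[1] += 1
                if use_occ:
                    for j in range(Jc):
                        t[j] = a_buf[j]

        # ---- lam0_trap / beta0 ----
        if use_scr:
            att[2] += 1
            win_att[2] += 1
            if cov_mode == COV_NONE:
                lam_p = lam0t * math.exp(step_lam0t * np.random.randn())
                if 0.0 < lam_p < lam0_max:
                    _lam0j_fill(lamj_prop, cov_mode, w, beta0, beta1, bait, lam_p)
                    new_scr = _scr_total(z, s, n_obs, Xt, Kt, yscr, lamj_prop, sigma)
                    dll = new_scr - cur_scr + math.log(lam_p) - math.log(lam0t)
                    if dll >= 0.0 or math.log(np.random.rand()) < dll:
                        lam0t = lam_p
                        for j in range(Jt):
                            lam0j[j] = lamj_prop[j]
                        cur_scr = new_scr
                        acc[2] += 1
                        win_acc[2] += 1
            else:
                b0_p = beta0 + step_beta0 * np.random.randn()
                _lam0j_fill(lamj_prop, cov_mode, w, b0_p, beta1, bait, lam0t)
                new_scr = _scr_total(z, s, n_obs, Xt, Kt, yscr, lamj_prop, sigma)
                dll = new_scr - cur_scr - (b0_p * b0_p - beta0 * beta0) / (2.0 * beta_sd * beta_sd)
                if dll >= 0.0 or math.log(np.random.rand()) < dll:
                    beta0 = b0_p
                    for j in range(Jt):
                        lam0j[j] = lamj_prop[j]
                    cur_scr = new_scr
                    acc[2] += 1
                    win_acc[2] += 1
                lam0t = math.exp(beta0)

        # ---- beta1 (within-model move, only when switched in) ----
        if use_scr and cov_mode != COV_NONE and w == 1:
            att[4] += 1
            win_att[4] += 1
            b1_p = beta1 + step_beta1 * np.random.randn()
            _lam0j_fill(lamj_prop, cov_mode, w, beta0, b1_p, bait, lam0t)
            new_scr = _scr_total(z, s, n_obs, Xt, Kt, yscr, lamj_prop, sigma)
            dll = new_scr - cur_scr - (b1_p * b1_p - beta1 * beta1) / (2.0 * beta_sd * beta_sd)
            if dll >= 0.0 or math.log(np.random.rand()) < dll:
                beta1 = b1_p
                for j in range(Jt):
                    lam0j[j] = lamj_prop[j]
                cur_scr = new_scr
                acc[4] += 1
                win_acc[4] += 1

        # ---- RJ toggle of the bait covariate ----
        if use_scr and cov_mode == COV_RJ:
            att[5] += 1
            if w == 0:
                b1_p = rj_prop_sd * np.random.randn()
                _lam0j_fill(lamj_prop, cov_mode, 1, beta0, b1_p, bait, lam0t)
                new_scr = _scr_total(z, s, n_obs, Xt, Kt, yscr, lamj_prop, sigma)
                # prior(beta1)/proposal(beta1); prior odds on w are 1 (0.5/0.5)
                lr = (new_scr - cur_scr
                      - b1_p * b1_p / (2.0 * beta_sd * beta_sd) - math.log(beta_sd)
                      + b1_p * b1_p / (2.0 * rj_prop_sd * rj_prop_sd) + math.log(rj_prop_sd))
                if lr >= 0.0 or math.log(np.random.rand()) < lr:
                    w = 1
                    beta1 = b1_p
                    for j in range(Jt):
                        lam0j[j] = lamj_prop[j]
                    cur_scr = new_scr
                    acc[5] += 1
            else:
                _lam0j_fill(lamj_prop, cov_mode, 0, beta0, beta1, bait, lam0t)
                new_scr = _scr_total(z, s, n_obs, Xt, Kt, yscr, lamj_prop, sigma)
                lr = (new_scr - cur_scr
                      + beta1 * beta1 / (2.0 * beta_sd * beta_sd) + math.log(beta_sd)
                      - beta1 * beta1 / (2.0 * rj_prop_sd * rj_prop_sd) - math.log(rj_prop_sd))
                if lr >= 0.0 or math.log(np.random.rand()) < lr:
                    w = 0
                    beta1 = 0.0
                    for j in range(Jt):
                        lam0j[j] = lamj_prop[j]
                    cur_scr = new_scr
                    acc[5] += 1

        # ---- lam0_cam ----
        if use_occ:
            att[3] += 1
            win_att[3] += 1
            lam_p = lam0c * math.exp(step_lam0c * np.random.randn())
            if 0.0 < lam_p < lam0_max:
                new_occ = _occ_total(z, s, Xc, Kc, yocc, lam_p, sigma, a_buf)
                dll = new_occ - cur_occ + math.log(lam_p) - math.log(lam0c)
                if dll >= 0.0 or math.log(np.random.rand()) < dll:
                    lam0c = lam_p
                    cur_occ = new_occ
                    acc[3] += 1
                    win_acc[3] += 1
                    for j in range(Jc):
                        t[j] = a_buf[j]

        # ---- adaptation during burn-in ----
        if it < n_burn and (it + 1) % 50 == 0:
            adapt_n += 1
            gain = 1.0 / math.sqrt(adapt_n)
            for i in range(M):
                if att_s_i[i] > 0:
                    steps_s[i] *= math.exp(gain * (acc_s_i[i] / att_s_i[i] - 0.35))
                acc_s_i[i] = 0.0
                att_s_i[i] = 0.0
            if win_att[1] > 0:
                step_sigma *= math.exp(gain * (win_acc[1] / win_att[1] - 0.35))
            if win_att[2] > 0:
                if cov_mode == COV_NONE:
                    step_lam0t *= math.exp(gain * (win_acc[2] / win_att[2] - 0.35))
                else:
                    step_beta0 *= math.exp(gain * (win_acc[2] / win_att[2] - 0.35))
            if win_att[3] > 0:
                step_lam0c *= math.exp(gain * (win_acc[3] / win_att[3] - 0.35))
            if win_att[4] > 0:
                step_beta1 *= math.exp(gain * (win_acc[4] / win_att[4] - 0.35))
            for k in range(6):
                win_acc[k] = 0.0
                win_att[k] = 0.0

        # refresh t from scratch occasionally to kill numerical drift
        if use_occ and (it + 1) % 200 == 0:
            _occ_total(z, s, Xc, Kc, yocc, lam0c, sigma, t)

        # ---- record ----
        if it >= n_burn:
            k = it - n_burn
            Nz = 0
            for i in range(M):
                Nz += z[i]
            draws[k, 0] = Nz
            draws[k, 1] = psi
            draws[k, 2] = sigma
            draws[k, 3] = lam0t if cov_mode == COV_NONE else math.exp(beta0)
            draws[k, 4] = lam0c
            draws[k, 5] = beta0
            draws[k, 6] = beta1
            draws[k, 7] = w
            if latent_thin > 0 and k % latent_thin == 0 and snap < n_snap:
                for i in range(M):
                    latent_z[snap, i] = z[i]
                    latent_s[snap, i, 0] = s[i, 0]
                    latent_s[snap, i, 1] = s[i, 1]
                snap += 1

    rates = np.zeros(6)
    for k in range(6):
        rates[k] = acc[k] / att[k] if att[k] > 0 else np.nan
    steps = np.array([steps_s.mean(), step_sigma, step_lam0t, step_lam0c,
                      step_beta0, step_beta1])
    return draws, latent_z, latent_s, rates, steps
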