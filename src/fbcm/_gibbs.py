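"""JIT-compiled Gibbs sweep for the hierarchical collapsing model.

All full conditionals are conjugate: normal for the location parameters
(intercept, covariate coefficients, within-family effect beta1,
between-family effect beta2, family effects phi), inverse-gamma for the two
variance components, exact two-point discrete updates for the spike
indicators alpha_k / gamma_k, and Beta(1 + ind, 2 - ind) for their
Bernoulli hyperparameters p_k / q_k.

A running residual vector is maintained across updates and refreshed
periodically to bound floating-point drift.  Indicator updates only touch
the offspring whose (r, s) indices reference the locus, supplied as a
CSR-style incidence structure, which keeps a sweep O(N + K + incidences).
"""

import numpy as np
from numba import njit


@njit(cache=True)
def run_gibbs_chain(
    y, X, fam, fam_sizes,
    dr, ds, ger, ges, r, s,
    loc_off, loc_idx, loc_d, loc_ge, K,
    n_iter, burn_in, thin, store_phi,
    mu, b1, b2, coef0, phi0, alpha0, gamma0, s2phi, s2eps,
    sigma2_beta, ig_a, ig_b,
    upd_mu, upd_b1, upd_b2, upd_coef, upd_alpha, upd_gamma,
    upd_phi, upd_s2phi, upd_s2eps,
    seed,
):
    np.random.seed(seed)
    N = y.shape[0]
    P = X.shape[1]
    M = fam_sizes.shape[0]

    coef = coef0.copy()
    phi = phi0.copy()
    alpha = alpha0.copy()
    gamma = gamma0.copy()
    p = np.full(K + 1, 0.5)
    q = np.full(K + 1, 0.5)

    n_kept = 0
    t = burn_in
    while t < n_iter:
        n_kept += 1
        t += thin

    mu_s = np.empty(n_kept)
    b1_s = np.empty(n_kept)
    b2_s = np.empty(n_kept)
    coef_s = np.empty((n_kept, P))
    alpha_s = np.empty((n_kept, K), dtype=np.uint8)
    gamma_s = np.empty((n_kept, K), dtype=np.uint8)
    p_s = np.empty((n_kept, K))
    q_s = np.empty((n_kept, K))
    s2phi_s = np.empty(n_kept)
    s2eps_s = np.empty(n_kept)
    n_phi = n_kept if store_phi else 0
    phi_s = np.empty((n_phi, M))

    resid = np.empty(N)
    xbuf = np.empty(N)
    fam_sum = np.empty(M)
    fam_delta = np.empty(M)

    for j in range(N):
        pred = mu + phi[fam[j]]
        for pp in range(P):
            pred += X[j, pp] * coef[pp]
        pred += b1 * (alpha[r[j]] * dr[j] + alpha[s[j]] * ds[j])
        pred += b2 * (gamma[r[j]] * ger[j] + gamma[s[j]] * ges[j])
        resid[j] = y[j] - pred

    kept = 0
    for t in range(n_iter):
        # ---- spike indicators and their Beta hyperparameters
        if upd_alpha:
            for k in range(1, K + 1):
                lo = loc_off[k - 1]
                hi = loc_off[k]
                a_cur = alpha[k]
                dll = 0.0
                for ii in range(lo, hi):
                    j = loc_idx[ii]
                    tj = b1 * loc_d[ii]
                    r0 = resid[j] + a_cur * tj
                    r1 = r0 - tj
                    dll += r0 * r0 - r1 * r1
                pk = min(max(p[k], 1e-12), 1.0 - 1e-12)
                logit = np.log(pk / (1.0 - pk)) + dll / (2.0 * s2eps)
                if logit > 35.0:
                    prob = 1.0
                elif logit < -35.0:
                    prob = 0.0
                else:
                    prob = 1.0 / (1.0 + np.exp(-logit))
                a_new = 1.0 if np.random.random() < prob else 0.0
                if a_new != a_cur:
                    for ii in range(lo, hi):
                        j = loc_idx[ii]
                        resid[j] -= (a_new - a_cur) * b1 * loc_d[ii]
                    alpha[k] = a_new
                p[k] = np.random.beta(1.0 + alpha[k], 2.0 - alpha[k])
        else:
            for k in range(1, K + 1):
                p[k] = np.random.beta(1.0 + alpha[k], 2.0 - alpha[k])

        if upd_gamma:
            for k in range(1, K + 1):
                lo = loc_off[k - 1]
                hi = loc_off[k]
                g_cur = gamma[k]
                dll = 0.0
                for ii in range(lo, hi):
                    j = loc_idx[ii]
                    tj = b2 * loc_ge[ii]
                    r0 = resid[j] + g_cur * tj
                    r1 = r0 - tj
                    dll += r0 * r0 - r1 * r1
                qk = min(max(q[k], 1e-12), 1.0 - 1e-12)
                logit = np.log(qk / (1.0 - qk)) + dll / (2.0 * s2eps)
                if logit > 35.0:
                    prob = 1.0
                elif logit < -35.0:
                    prob = 0.0
                else:
                    prob = 1.0 / (1.0 + np.exp(-logit))
                g_new = 1.0 if np.random.random() < prob else 0.0
                if g_new != g_cur:
                    for ii in range(lo, hi):
                        j = loc_idx[ii]
                        resid[j] -= (g_new - g_cur) * b2 * loc_ge[ii]
                    gamma[k] = g_new
                q[k] = np.random.beta(1.0 + gamma[k], 2.0 - gamma[k])
        else:
            for k in range(1, K + 1):
                q[k] = np.random.beta(1.0 + gamma[k], 2.0 - gamma[k])

        # ---- intercept
        if upd_mu:
            sr = mu * N
            for j in range(N):
                sr += resid[j]
            prec = N / s2eps + 1.0 / sigma2_beta
            mean = (sr / s2eps) / prec
            mu_new = mean + np.random.normal() / np.sqrt(prec)
            dmu = mu_new - mu
            for j in range(N):
                resid[j] -= dmu
            mu = mu_new

        # ---- covariate coefficients (coordinate-wise)
        if upd_coef:
            for pp in range(P):
                sx2 = 0.0
                sxr = 0.0
                for j in range(N):
                    x = X[j, pp]
                    sx2 += x * x
                    sxr += x * (resid[j] + coef[pp] * x)
                prec = sx2 / s2eps + 1.0 / sigma2_beta
                mean = (sxr / s2eps) / prec
                cnew = mean + np.random.normal() / np.sqrt(prec)
                dc = cnew - coef[pp]
                for j in range(N):
                    resid[j] -= dc * X[j, pp]
                coef[pp] = cnew

        # ---- within-family effect beta1
        if upd_b1:
            sx2 = 0.0
            sxr = 0.0
            for j in range(N):
                x = alpha[r[j]] * dr[j] + alpha[s[j]] * ds[j]
                xbuf[j] = x
                sx2 += x * x
                sxr += x * (resid[j] + b1 * x)
            prec = sx2 / s2eps + 1.0 / sigma2_beta
            mean = (sxr / s2eps) / prec
            b1_new = mean + np.random.normal() / np.sqrt(prec)
            db = b1_new - b1
            for j in range(N):
                resid[j] -= db * xbuf[j]
            b1 = b1_new

        # ---- between-family effect beta2
        if upd_b2:
            sx2 = 0.0
            sxr = 0.0
            for j in range(N):
                x = gamma[r[j]] * ger[j] + gamma[s[j]] * ges[j]
                xbuf[j] = x
                sx2 += x * x
                sxr += x * (resid[j] + b2 * x)
            prec = sx2 / s2eps + 1.0 / sigma2_beta
            mean = (sxr / s2eps) / prec
            b2_new = mean + np.random.normal() / np.sqrt(prec)
            db = b2_new - b2
            for j in range(N):
                resid[j] -= db * xbuf[j]
            b2 = b2_new

        # ---- family random effects
        if upd_phi:
            for i in range(M):
                fam_sum[i] = 0.0
            for j in range(N):
                fam_sum[fam[j]] += resid[j]
            for i in range(M):
                ni = fam_sizes[i]
                tot = fam_sum[i] + ni * phi[i]
                prec = ni / s2eps + 1.0 / s2phi
                mean = (tot / s2eps) / prec
                phi_new = mean + np.random.normal() / np.sqrt(prec)
                fam_delta[i] = phi_new - phi[i]
                phi[i] = phi_new
            for j in range(N):
                resid[j] -= fam_delta[fam[j]]

        # ---- variance components
        if upd_s2phi:
            ssp = 0.0
            for i in range(M):
                ssp += phi[i] * phi[i]
            gdraw = np.random.gamma(ig_a + 0.5 * M, 1.0 / (ig_b + 0.5 * ssp))
            s2phi = 1.0 / max(gdraw, 1e-300)
        if upd_s2eps:
            sse = 0.0
            for j in range(N):
                sse += resid[j] * resid[j]
            gdraw = np.random.gamma(ig_a + 0.5 * N, 1.0 / (ig_b + 0.5 * sse))
            s2eps = 1.0 / max(gdraw, 1e-300)

        # ---- bound floating-point drift of the running residual
        if (t + 1) % 512 == 0:
            for j in range(N):
                pred = mu + phi[fam[j]]
                for pp in range(P):
                    pred += X[j, pp] * coef[pp]
                pred += b1 * (alpha[r[j]] * dr[j] + alpha[s[j]] * ds[j])
                pred += b2 * (gamma[r[j]] * ger[j] + gamma[s[j]] * ges[j])
                resid[j] = y[j] - pred

        # ---- record
        if t >= burn_in and (t - burn_in) % thin == 0:
            mu_s[kept] = mu
            b1_s[kept] = b1
            b2_s[kept] = b2
            for pp in range(P):
                coef_s[kept, pp] = coef[pp]
            for k in range(K):
                alpha_s[kept, k] = np.uint8(alpha[k + 1])
                gamma_s[kept, k] = np.uint8(gamma[k + 1])
                p_s[kept, k] = p[k + 1]
                q_s[kept, k] = q[k + 1]
            s2phi_s[kept] = s2phi
            s2eps_s[kept] = s2eps
            if store_phi:
                for i in range(M):
                    phi_s[kept, i] = phi[i]
            kept += 1

    return (mu_s, b1_s, b2_s, coef_s, alpha_s, gamma_s, p_s, q_s,
            s2phi_s, s2eps_s, phi_s)
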