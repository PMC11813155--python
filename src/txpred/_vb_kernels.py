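"""Numba-compiled coordinate sweeps for the variational regressions."""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def varbvs_sweep(XT, xty, d, alpha, mu, Xr, sige, sa2, logodds):
    """One full coordinate-ascent sweep of the spike-and-slab approximation.

    ``alpha`` (PIPs), ``mu`` (slab means) and ``Xr = X (alpha*mu)`` are
    updated in place. Slab variance is ``sa2 * sige`` (scaled parametrization).
    """
    m, n = XT.shape
    for j in range(m):
        s2 = sige / (d[j] + 1.0 / sa2)
        rj = alpha[j] * mu[j]
        dot = 0.0
        for i in range(n):
            dot += XT[j, i] * Xr[i]
        num = xty[j] - dot + d[j] * rj
        mu_new = s2 * num / sige
        lo = logodds + 0.5 * np.log(s2 / (sa2 * sige)) + 0.5 * mu_new * mu_new / s2
        if lo > 35.0:
            a_new = 1.0
        elif lo < -35.0:
            a_new = 0.0
        else:
            a_new = 1.0 / (1.0 + np.exp(-lo))
        diff = a_new * mu_new - rj
        for i in range(n):
            Xr[i] += XT[j, i] * diff
        alpha[j] = a_new
        mu[j] = mu_new


@njit(cache=True)
def mrash_sweep(XT, xty, d, beta, Xr, phi, sige, sa2, logpi):
    """One coordinate sweep of the mixture-of-normals posterior updates.

    Slab variances are *scaled by the residual variance*: component k's
    prior is N(0, sige * sa2[k]) (the standard parametrization, which ties
    slab widths to the noise level and removes the overfit-by-shrinking-
    sigma_e degeneracy). ``beta`` holds posterior means, ``phi`` (m x K)
    the responsibilities, ``Xr = X beta``.

    Returns (S, A, kl_log, sum_incl):
      S[j]     = E[beta_j^2] (posterior second moment),
      A        = sum_{j,k>=1} phi_jk (v_jk + m_jk^2) / sa2[k]  (sige update),
      kl_log   = sum_{j,k>=1} phi_jk log(u_jk / sa2[k]), u = v/sige,
      sum_incl = sum_j (1 - phi_j0).
    """
    m, n = XT.shape
    K = sa2.shape[0]
    S = np.zeros(m)
    A = 0.0
    kl_log = 0.0
    sum_incl = 0.0
    logw = np.empty(K)
    uk = np.empty(K)
    mk = np.empty(K)
    for j in range(m):
        dot = 0.0
        for i in range(n):
            dot += XT[j, i] * Xr[i]
        num = xty[j] - dot + d[j] * beta[j]
        logw[0] = logpi[0]
        uk[0] = 0.0
        mk[0] = 0.0
        maxl = logw[0]
        for k in range(1, K):
            u = 1.0 / (d[j] + 1.0 / sa2[k])
            mval = u * num
            uk[k] = u
            mk[k] = mval
            logw[k] = (
                logpi[k] + 0.5 * np.log(u / sa2[k]) + 0.5 * mval * mval / (sige * u)
            )
            if logw[k] > maxl:
                maxl = logw[k]
        tot = 0.0
        for k in range(K):
            w = np.exp(logw[k] - maxl)
            logw[k] = w
            tot += w
        b_new = 0.0
        s_new = 0.0
        for k in range(K):
            p = logw[k] / tot
            phi[j, k] = p
            if k > 0 and p > 1e-300:
                v = sige * uk[k]
                b_new += p * mk[k]
                s_new += p * (v + mk[k] * mk[k])
                A += p * (v + mk[k] * mk[k]) / sa2[k]
                kl_log += p * np.log(uk[k] / sa2[k])
                sum_incl += p
        diff = b_new - beta[j]
        for i in range(n):
            Xr[i] += XT[j, i] * diff
        beta[j] = b_new
        S[j] = s_new
    return S, A, kl_log, sum_incl
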