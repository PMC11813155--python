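"""Numba-compiled Gibbs sweep for (grouped) spike-and-slab regression.

A single kernel serves both the one-group sampler and the two-group
gene-set-informed variant: ``group`` labels each column and every group
carries its own inclusion probability and slab variance. The kernel runs
the entire chain (coordinate sweeps plus hyperparameter updates) so the
per-coordinate loop never crosses the Python boundary.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def spike_slab_gibbs(
    XT,          # (m, n) transposed design, row-contiguous columns
    y,           # (n,) centered response
    Xtest,       # (n_test, m) centered test design (may be 0 x m)
    group,       # (m,) int group label per column
    n_groups,    # int
    pi,          # (n_groups,) initial inclusion probabilities
    sigb,        # (n_groups,) initial slab variances
    sige,        # float initial residual variance
    beta_a, beta_b,   # Beta prior counts for pi
    df_b, Sb,         # scaled-inv-chi2 df and per-group scale for slab var
    df_e, Se,         # scaled-inv-chi2 df and scale for residual var
    fix_pi, fix_sigb, fix_sige,   # 0/1 flags: hold hyperparameter fixed
    n_iter, burn_in, thin, seed,
):
    m, n = XT.shape
    n_test = Xtest.shape[0]
    np.random.seed(seed)

    xtx = np.empty(m)
    for j in range(m):
        s = 0.0
        for i in range(n):
            s += XT[j, i] * XT[j, i]
        xtx[j] = s

    beta = np.zeros(m)
    delta = np.zeros(m, dtype=np.int8)
    r = y.copy()

    n_ret = (n_iter - burn_in) // thin
    pip_acc = np.zeros(m)
    beta_acc = np.zeros(m)
    sige_d = np.empty(n_ret)
    sigb_d = np.empty((n_ret, n_groups))
    pi_d = np.empty((n_ret, n_groups))
    pred_d = np.zeros((n_ret, n_test))

    mg = np.zeros(n_groups, dtype=np.int64)
    for j in range(m):
        mg[group[j]] += 1

    k_active = np.zeros(n_groups, dtype=np.int64)
    ssq_active = np.zeros(n_groups)

    for it in range(n_iter):
        # --- joint (indicator, effect) update per coordinate ---
        for j in range(m):
            g = group[j]
            old = beta[j]
            rhs = 0.0
            for i in range(n):
                rhs += XT[j, i] * r[i]
            rhs += xtx[j] * old
            C = xtx[j] + sige / sigb[g]
            v = sige / C
            mu = rhs / C
            logodds = (
                np.log(pi[g] / (1.0 - pi[g]))
                + 0.5 * np.log(v / sigb[g])
                + 0.5 * mu * mu / v
            )
            if logodds > 35.0:
                p = 1.0
            elif logodds < -35.0:
                p = 0.0
            else:
                p = 1.0 / (1.0 + np.exp(-logodds))
            if np.random.random() < p:
                newb = mu + np.sqrt(v) * np.random.standard_normal()
                delta[j] = 1
            else:
                newb = 0.0
                delta[j] = 0
            if newb != old:
                diff = old - newb
                for i in range(n):
                    r[i] += XT[j, i] * diff
                beta[j] = newb

        # periodic residual refresh against floating-point drift
        if (it + 1) % 5000 == 0:
            for i in range(n):
                s = y[i]
                for j in range(m):
                    if beta[j] != 0.0:
                        s -= XT[j, i] * beta[j]
                r[i] = s

        # --- hyperparameters ---
        for g in range(n_groups):
            k_active[g] = 0
            ssq_active[g] = 0.0
        for j in range(m):
            if delta[j] == 1:
                g = group[j]
                k_active[g] += 1
                ssq_active[g] += beta[j] * beta[j]

        if fix_pi == 0:
            for g in range(n_groups):
                pi[g] = np.random.beta(
                    beta_a + k_active[g], beta_b + mg[g] - k_active[g]
                )
                if pi[g] < 1e-8:
                    pi[g] = 1e-8
                elif pi[g] > 1.0 - 1e-8:
                    pi[g] = 1.0 - 1e-8
        if fix_sigb == 0:
            for g in range(n_groups):
                sigb[g] = (df_b * Sb[g] + ssq_active[g]) / np.random.chisquare(
                    df_b + k_active[g]
                )
                if sigb[g] < 1e-12:
                    sigb[g] = 1e-12
        if fix_sige == 0:
            rss = 0.0
            for i in range(n):
                rss += r[i] * r[i]
            sige = (df_e * Se + rss) / np.random.chisquare(df_e + n)
            if sige < 1e-12:
                sige = 1e-12

        # --- retain ---
        if it >= burn_in and (it - burn_in) % thin == 0:
            idx = (it - burn_in) // thin
            for j in range(m):
                pip_acc[j] += delta[j]
                beta_acc[j] += beta[j]
            sige_d[idx] = sige
            for g in range(n_groups):
                sigb_d[idx, g] = sigb[g]
                pi_d[idx, g] = pi[g]
            for t in range(n_test):
                s = 0.0
                for j in range(m):
                    if beta[j] != 0.0:
                        s += Xtest[t, j] * beta[j]
                pred_d[idx, t] = s

    pip = pip_acc / n_ret
    beta_mean = beta_acc / n_ret
    return pip, beta_mean, sige_d, sigb_d, pi_d, pred_d
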