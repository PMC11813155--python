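"""Independent reference computations used by the tests.

These deliberately avoid the package's own code paths: exhaustive model
enumeration for spike-and-slab posteriors, normal-equation least squares,
and closed-form ridge/BLUP solutions.
"""

from itertools import product

import numpy as np


def enumeration_posterior(Xc, yc, pi, sigma_b2, sigma_e2, X_test=None, groups=None):
    """Exact spike-and-slab posterior by enumerating all 2^m models.

    ``pi``/``sigma_b2`` may be scalars or per-group values with ``groups``
    labelling columns. Returns (pips, predictions or None).
    Marginal likelihood per model: y ~ N(0, sigma_b2 X_g X_g^T + sigma_e2 I).
    """
    n, m = Xc.shape
    if groups is None:
        groups = np.zeros(m, int)
    pi = np.atleast_1d(np.asarray(pi, float))
    sigma_b2 = np.atleast_1d(np.asarray(sigma_b2, float))
    gammas = list(product([0, 1], repeat=m))
    logps = np.empty(len(gammas))
    means = []
    for i, g in enumerate(gammas):
        idx = [j for j in range(m) if g[j]]
        S = sigma_e2 * np.eye(n)
        for j in idx:
            S += sigma_b2[groups[j]] * np.outer(Xc[:, j], Xc[:, j])
        _, logdet = np.linalg.slogdet(S)
        ll = -0.5 * (n * np.log(2 * np.pi) + logdet + yc @ np.linalg.solve(S, yc))
        lp = sum(
            np.log(pi[groups[j]]) if g[j] else np.log(1 - pi[groups[j]])
            for j in range(m)
        )
        logps[i] = ll + lp
        if X_test is not None:
            if idx:
                Xg = Xc[:, idx]
                V = np.diag([sigma_b2[groups[j]] for j in idx])
                cov = V @ Xg.T
                post_mean = cov @ np.linalg.solve(Xg @ cov + sigma_e2 * np.eye(n), yc)
                means.append(X_test[:, idx] @ post_mean)
            else:
                means.append(np.zeros(X_test.shape[0]))
    w = np.exp(logps - logps.max())
    w /= w.sum()
    pips = np.zeros(m)
    for wi, g in zip(w, gammas):
        pips += wi * np.array(g)
    preds = None
    if X_test is not None:
        preds = np.einsum("i,ij->j", w, np.array(means))
    return pips, preds


def ols_predictions(X_train, y_train, X_eval):
    """Least-squares fit with intercept via lstsq on centered data."""
    mu = X_train.mean(axis=0)
    ym = y_train.mean()
    b = np.linalg.lstsq(X_train - mu, y_train - ym, rcond=None)[0]
    return (X_eval - mu) @ b + ym


def ridge_closed_form(Xc, yc, lam_prime):
    return np.linalg.solve(Xc.T @ Xc + lam_prime * np.eye(Xc.shape[1]), Xc.T @ yc)


def blup_closed_form(T_train, T_cross, y_train, sigma_t2, sigma_e2):
    """Conditional-mean random effects for training and held-out lines."""
    yc = y_train - y_train.mean()
    A = np.linalg.solve(sigma_t2 * T_train + sigma_e2 * np.eye(len(yc)),
                        yc)
    return sigma_t2 * T_train @ A, sigma_t2 * T_cross @ A
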