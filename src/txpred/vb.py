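"""Variational spike-and-slab and mixture-of-normals regression.

Two deterministic alternatives to the MCMC samplers:

* :func:`fit_varbvs` — fully-factorized coordinate-ascent variational
  inference for the spike-and-slab model, run once per candidate prior
  log-odds value; the per-state approximations are combined with normalized
  importance weights derived from their evidence lower bounds (ELBOs).
* :func:`fit_mrash` — empirical-Bayes multiple regression with a scale
  mixture-of-normals prior (a point mass at zero plus K - 1 Gaussian
  components); mixture weights are estimated from the data by coordinate
  ascent and the fit is conventionally initialized from lasso estimates.

Both are exact coordinate ascent on their ELBOs, so the ELBO trace must be
non-decreasing; a decrease beyond round-off tolerance raises (it would mean
an update bug, not a modelling failure). Same inputs give bit-identical
outputs — there is no randomness anywhere in this module.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._vb_kernels import mrash_sweep, varbvs_sweep

__all__ = ["VariationalFit", "fit_varbvs", "fit_mrash", "default_logodds_grid"]

_ELBO_VIOLATION_TOL = 1e-6


@dataclass
class VariationalFit:
    method: str
    pip: np.ndarray
    effect_means: np.ndarray
    elbo_trace: list
    converged: bool
    x_mean: np.ndarray
    y_mean: float
    hyper_grid: list = field(default_factory=list)
    importance_weights: np.ndarray | None = None
    mixture_weights: np.ndarray | None = None
    sigma_e2: float | None = None
    intercept_only: bool = False

    def predict(self, X_new: np.ndarray) -> np.ndarray:
        X_new = np.atleast_2d(np.asarray(X_new, float))
        return (X_new - self.x_mean) @ self.effect_means + self.y_mean


def _check_monotone(trace: list[float], context: str) -> None:
    for a, b in zip(trace, trace[1:]):
        if b < a - _ELBO_VIOLATION_TOL * (1.0 + abs(a)):
            raise RuntimeError(
                f"ELBO decreased in {context}: {a:.10g} -> {b:.10g} (update bug)"
            )


def default_logodds_grid(m: int, size: int = 20) -> np.ndarray:
    """log-odds values spanning prior inclusion probability 1/m to 1/2."""
    p = np.geomspace(1.0 / m, 0.5, size)
    return np.log(p / (1.0 - p))


# ---------------------------------------------------------------------------
# VARBVS-style CAVI


def _varbvs_elbo(yc, Xr, d, alpha, mu, s2, sige, sa2, pi):
    # s2 is passed explicitly: the variational variances from the sweep,
    # evaluated before any hyperparameter move (keeps the trace an exact
    # coordinate-ascent objective, hence provably monotone)
    n = len(yc)
    varB = alpha * (s2 + mu**2) - (alpha * mu) ** 2
    rss = np.sum((yc - Xr) ** 2)
    a = np.clip(alpha, 1e-12, 1 - 1e-12)
    elbo = (
        -0.5 * n * np.log(2 * np.pi * sige)
        - (rss + np.sum(d * varB)) / (2 * sige)
        + np.sum(a * np.log(pi / a) + (1 - a) * np.log((1 - pi) / (1 - a)))
        + 0.5 * np.sum(alpha * (1 + np.log(s2 / (sa2 * sige))
                                - (s2 + mu**2) / (sa2 * sige)))
    )
    return float(elbo)


def _run_varbvs_state(XT, xty, yc, d, logodds, sige0, sa20, tol, max_outer,
                      update_hyper):
    m = XT.shape[0]
    pi = 1.0 / (1.0 + np.exp(-logodds))
    alpha = np.full(m, pi)
    mu = np.zeros(m)
    Xr = XT.T @ (alpha * mu)
    sige, sa2 = sige0, sa20
    trace = []
    converged = False
    for _ in range(max_outer):
        varbvs_sweep(XT, xty, d, alpha, mu, Xr, sige, sa2, logodds)
        s2 = sige / (d + 1.0 / sa2)  # variational variances used by the sweep
        if update_hyper:
            varB = alpha * (s2 + mu**2) - (alpha * mu) ** 2
            rss = np.sum((yc - Xr) ** 2)
            sum_a = np.sum(alpha)
            e2 = np.sum(alpha * (s2 + mu**2))
            sige = (rss + np.sum(d * varB) + e2 / sa2) / (len(yc) + sum_a)
            if sum_a > 1e-10:
                sa2 = max(e2 / (sige * sum_a), 1e-12)
        elbo = _varbvs_elbo(yc, Xr, d, alpha, mu, s2, sige, sa2, pi)
        trace.append(elbo)
        _check_monotone(trace, f"varbvs state logodds={logodds:.3f}")
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) < tol * (1 + abs(trace[-2])):
            converged = True
            break
    return alpha, mu, sige, sa2, trace, converged


def fit_varbvs(
    X: np.ndarray,
    y: np.ndarray,
    logodds_grid: np.ndarray | None = None,
    tol: float = 1e-8,
    max_outer: int = 1000,
    X_test: np.ndarray | None = None,
    fixed: dict | None = None,
) -> VariationalFit:
    """Spike-and-slab regression by CAVI over a prior-inclusion grid.

    Each grid state gets its own coordinate-ascent run (residual and slab
    variances re-estimated within the state unless ``fixed`` pins them);
    states are averaged with importance weights proportional to
    ``exp(ELBO_state)``. ``fixed`` may supply ``pi``, ``sigma_beta2`` and
    ``sigma_e2`` for validation against exact enumeration posteriors.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    n, m = X.shape
    fixed = fixed or {}
    x_mean, y_mean = X.mean(axis=0), y.mean()
    Xc, yc = X - x_mean, y - y_mean
    XT = np.ascontiguousarray(Xc.T)
    xty = Xc.T @ yc
    d = np.einsum("ij,ij->j", Xc, Xc)

    if "pi" in fixed:
        p = float(fixed["pi"])
        logodds_grid = np.array([np.log(p / (1 - p))])
    elif logodds_grid is None:
        logodds_grid = default_logodds_grid(m)
    logodds_grid = np.asarray(logodds_grid, float)
    if logodds_grid.size == 0:
        raise ValueError("logodds grid must be non-empty")

    update_hyper = not ({"sigma_beta2", "sigma_e2"} & fixed.keys())
    sige0 = float(fixed.get("sigma_e2", np.var(yc, ddof=1)))
    if "sigma_beta2" in fixed:
        sa20 = float(fixed["sigma_beta2"]) / sige0
    else:
        sa20 = 1.0

    states = []
    elbos = np.empty(len(logodds_grid))
    traces = []
    all_conv = True
    for i, lo in enumerate(logodds_grid):
        alpha, mu, sige, sa2, trace, conv = _run_varbvs_state(
            XT, xty, yc, d, float(lo), sige0, sa20, tol, max_outer, update_hyper
        )
        states.append((alpha, mu, sige, sa2))
        elbos[i] = trace[-1]
        traces.append(trace)
        all_conv &= conv
    w = np.exp(elbos - elbos.max())
    w /= w.sum()
    pip = sum(wi * s[0] for wi, s in zip(w, states))
    beta = sum(wi * s[0] * s[1] for wi, s in zip(w, states))
    return VariationalFit(
        method="varbvs",
        pip=pip,
        effect_means=beta,
        elbo_trace=traces,
        converged=all_conv,
        x_mean=x_mean,
        y_mean=y_mean,
        hyper_grid=[
            {"logodds": float(lo), "sigma_e2": s[2], "sa2": s[3], "elbo": float(e)}
            for lo, s, e in zip(logodds_grid, states, elbos)
        ],
        importance_weights=w,
        sigma_e2=float(sum(wi * s[2] for wi, s in zip(w, states))),
    )


# ---------------------------------------------------------------------------
# Mixture-of-normals empirical Bayes (mr.ash-style)


def default_sigma_grid(X: np.ndarray, y: np.ndarray, K: int = 20) -> np.ndarray:
    """Grid of prior effect variances: 0 plus a geometric ladder.

    The ladder runs from four times the squared standard error of a
    univariate coefficient (effects below twice their standard error are
    statistically indistinguishable from zero; representing them as slabs
    would leave the mixture-weight objective flat and the spike weight
    unidentifiable) up to twice the largest squared univariate effect.
    """
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    d = np.einsum("ij,ij->j", Xc, Xc)
    d_safe = np.where(d > 0, d, 1.0)
    bmax2 = float(np.max((Xc.T @ yc / d_safe) ** 2))
    s2_min = 4.0 * float(np.var(yc, ddof=1) / np.mean(d_safe))
    if bmax2 <= 0 or s2_min <= 0:
        return np.concatenate([[0.0], np.geomspace(1e-6, 1.0, K - 1)])
    hi = max(bmax2 * 2, s2_min * 4)
    return np.concatenate([[0.0], np.geomspace(s2_min, hi, K - 1)])


def _mrash_elbo(yc, Xr, d, beta, S, A, kl_log, sum_incl, sige_old, phi, logpi, sige):
    # evaluated at the q produced by the sweep (whose Gaussian variances were
    # formed under sige_old) and the current hyperparameters (sige, pi)
    n = len(yc)
    varB = S - beta**2
    rss = np.sum((yc - Xr) ** 2)
    phi_safe = np.clip(phi, 1e-300, 1.0)
    # phi == 0 contributes nothing even when the matching prior weight is 0
    with np.errstate(invalid="ignore"):
        cat = np.nansum(np.where(phi > 0, phi * (logpi[None, :] - np.log(phi_safe)), 0.0))
    gauss = 0.5 * (
        sum_incl * (1.0 + np.log(sige_old / sige)) + kl_log - A / sige
    )
    return float(
        -0.5 * n * np.log(2 * np.pi * sige)
        - (rss + np.sum(d * varB)) / (2 * sige)
        + cat
        + gauss
    )


def fit_mrash(
    X: np.ndarray,
    y: np.ndarray,
    sigma_grid: np.ndarray | None = None,
    beta_init: np.ndarray | None = None,
    tol: float = 1e-8,
    max_outer: int = 1000,
    X_test: np.ndarray | None = None,
    fix_weights: np.ndarray | None = None,
    fix_sigma_e2: float | None = None,
) -> VariationalFit:
    """Mixture-of-normals empirical-Bayes regression by coordinate ascent.

    The prior is pi_0 delta_0 + sum_k pi_k N(0, sigma_k^2) over a fixed
    variance grid (which must include 0); the weights pi are estimated
    unless ``fix_weights`` pins them. ``beta_init`` (typically the lasso
    solution at its CV-selected penalty) warm-starts the posterior means.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    n, m = X.shape
    x_mean, y_mean = X.mean(axis=0), y.mean()
    Xc, yc = X - x_mean, y - y_mean
    XT = np.ascontiguousarray(Xc.T)
    xty = Xc.T @ yc
    d = np.einsum("ij,ij->j", Xc, Xc)

    if sigma_grid is None:
        sigma_grid = default_sigma_grid(X, y)
    sigma_grid = np.asarray(sigma_grid, float)
    if sigma_grid[0] != 0.0:
        raise ValueError("sigma grid must start with the point mass at 0")
    K = len(sigma_grid)
    sige = float(fix_sigma_e2) if fix_sigma_e2 is not None else float(np.var(yc, ddof=1))
    # internal slab variances are scaled by the residual variance; the public
    # grid is in raw effect-variance units at the initial noise estimate
    sa2 = sigma_grid / sige

    if fix_weights is not None:
        pi = np.asarray(fix_weights, float)
        if len(pi) != K or abs(pi.sum() - 1) > 1e-8:
            raise ValueError("fix_weights must match the grid and sum to 1")
    else:
        pi = np.full(K, 1.0 / K)
    beta = np.zeros(m) if beta_init is None else np.asarray(beta_init, float).copy()
    if beta.shape != (m,):
        raise ValueError("beta_init must have length m")
    Xr = Xc @ beta
    phi = np.zeros((m, K))

    trace = []
    converged = False
    with np.errstate(divide="ignore"):
        logpi = np.log(pi)
    for _ in range(max_outer):
        S, A, kl_log, sum_incl = mrash_sweep(
            XT, xty, d, beta, Xr, phi, sige, sa2, logpi
        )
        sige_old = sige
        if fix_weights is None:
            pi = phi.mean(axis=0)
            with np.errstate(divide="ignore"):
                logpi = np.log(np.clip(pi, 1e-300, 1.0))
        if fix_sigma_e2 is None:
            rss_term = np.sum((yc - Xr) ** 2) + np.sum(d * (S - beta**2))
            sige = float((rss_term + A) / (n + sum_incl))
        elbo = _mrash_elbo(yc, Xr, d, beta, S, A, kl_log, sum_incl, sige_old,
                           phi, logpi, sige)
        trace.append(elbo)
        _check_monotone(trace, "mrash")
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) < tol * (1 + abs(trace[-2])):
            converged = True
            break
    pip = 1.0 - phi[:, 0]
    return VariationalFit(
        method="mrash",
        pip=pip,
        effect_means=beta.copy(),
        elbo_trace=[trace],
        converged=converged,
        x_mean=x_mean,
        y_mean=y_mean,
        mixture_weights=pi.copy(),
        sigma_e2=sige,
        intercept_only=bool(np.all(beta == 0)),
    )
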