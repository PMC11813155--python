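"""Uniform predictor interface over all models, plus a plug-in registry.

Every adapter has the signature

    fn(X_train, y_train, X_test, seed, **config) -> FitOutcome

taking raw (uncentered) expression sub-matrices; centering/standardization
happens inside each model using training statistics only. Third-party
learners (tree ensembles, neural networks, ...) can join a comparison via
:func:`register_method` without touching the evaluation code.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dimreduce import fit_pcr, fit_plsr
from .mcmc import (
    BAYESC_SCHEDULE,
    TBLUP_SCHEDULE,
    fit_bayesc,
    fit_go_bayesc,
    fit_go_tblup,
    fit_tblup,
)
from .penalized import fit_lasso, fit_ridge
from .vb import fit_mrash, fit_varbvs

__all__ = ["FitOutcome", "REGISTRY", "register_method", "get_methods",
           "standardize_train_test"]


@dataclass
class FitOutcome:
    predictions: np.ndarray | None
    failed: bool = False
    failure_cause: str | None = None


def standardize_train_test(X_train, X_test):
    """Column-standardize by training stats; drop zero-variance training genes."""
    mu = X_train.mean(axis=0)
    sd = X_train.std(axis=0, ddof=1)
    keep = sd > 0
    W_tr = (X_train[:, keep] - mu[keep]) / sd[keep]
    W_te = (X_test[:, keep] - mu[keep]) / sd[keep]
    return W_tr, W_te, keep


def _pcr(X_train, y_train, X_test, seed, **cfg):
    fit = fit_pcr(X_train, y_train, max_k=cfg.get("max_k"),
                  cv_folds=cfg.get("cv_folds", 5), seed=seed)
    return FitOutcome(fit.predict(X_test), failed=fit.intercept_only,
                      failure_cause="intercept-only" if fit.intercept_only else None)


def _plsr(X_train, y_train, X_test, seed, **cfg):
    fit = fit_plsr(X_train, y_train, max_k=cfg.get("max_k"),
                   cv_folds=cfg.get("cv_folds", 5),
                   max_iter=cfg.get("max_iter", 100), seed=seed)
    if not fit.converged:
        return FitOutcome(None, failed=True, failure_cause="non-convergence")
    return FitOutcome(fit.predict(X_test), failed=fit.intercept_only,
                      failure_cause="intercept-only" if fit.intercept_only else None)


def _ridge(X_train, y_train, X_test, seed, **cfg):
    fit = fit_ridge(X_train, y_train, seed=seed, **cfg)
    return FitOutcome(fit.predict(X_test))


def _lasso(X_train, y_train, X_test, seed, **cfg):
    fit = fit_lasso(X_train, y_train, seed=seed, **cfg)
    return FitOutcome(fit.predict(X_test), failed=fit.intercept_only,
                      failure_cause="intercept-only" if fit.intercept_only else None)


def _bayesc(X_train, y_train, X_test, seed, **cfg):
    sched = cfg.get("schedule", BAYESC_SCHEDULE)
    fit = fit_bayesc(X_train, y_train, calib=cfg.get("calibration"),
                     sched=sched, X_test=X_test, seed=seed)
    return FitOutcome(fit.predictions)


def _go_bayesc(X_train, y_train, X_test, seed, **cfg):
    fit = fit_go_bayesc(X_train, y_train, cfg["go_mask"],
                        calib=cfg.get("calibration"),
                        sched=cfg.get("schedule", BAYESC_SCHEDULE),
                        X_test=X_test, seed=seed)
    return FitOutcome(fit.predictions)


def _varbvs(X_train, y_train, X_test, seed, **cfg):
    fit = fit_varbvs(X_train, y_train,
                     logodds_grid=cfg.get("logodds_grid"),
                     tol=cfg.get("tol", 1e-8),
                     max_outer=cfg.get("max_outer", 1000))
    return FitOutcome(fit.predict(X_test))


def _mrash(X_train, y_train, X_test, seed, **cfg):
    # the documented initialization path: lasso estimates at the CV penalty
    lasso = fit_lasso(X_train, y_train, seed=seed)
    fit = fit_mrash(X_train, y_train,
                    sigma_grid=cfg.get("sigma_grid"),
                    beta_init=lasso.coefficients,
                    tol=cfg.get("tol", 1e-8),
                    max_outer=cfg.get("max_outer", 1000))
    return FitOutcome(fit.predict(X_test), failed=fit.intercept_only,
                      failure_cause="intercept-only" if fit.intercept_only else None)


def _tblup(X_train, y_train, X_test, seed, **cfg):
    W_tr, W_te, _ = standardize_train_test(X_train, X_test)
    m = W_tr.shape[1]
    W = np.vstack([W_tr, W_te])
    T = W @ W.T / m
    n_tr = len(W_tr)
    fit = fit_tblup(T, y_train, np.arange(n_tr),
                    np.arange(n_tr, n_tr + len(W_te)),
                    calib=cfg.get("calibration"),
                    sched=cfg.get("schedule", TBLUP_SCHEDULE), seed=seed)
    return FitOutcome(fit.predictions)


def _go_tblup(X_train, y_train, X_test, seed, **cfg):
    W_tr, W_te, keep = standardize_train_test(X_train, X_test)
    mask = np.asarray(cfg["go_mask"], bool)[keep]
    m = W_tr.shape[1]
    W = np.vstack([W_tr, W_te])
    T_go = W[:, mask] @ W[:, mask].T / m
    T_not = W[:, ~mask] @ W[:, ~mask].T / m
    n_tr = len(W_tr)
    fit = fit_go_tblup(T_go, T_not, y_train, np.arange(n_tr),
                       np.arange(n_tr, n_tr + len(W_te)),
                       calib=cfg.get("calibration"),
                       sched=cfg.get("schedule", TBLUP_SCHEDULE), seed=seed)
    return FitOutcome(fit.predictions)


REGISTRY: dict = {
    "pcr": _pcr,
    "plsr": _plsr,
    "ridge": _ridge,
    "lasso": _lasso,
    "bayesc": _bayesc,
    "go_bayesc": _go_bayesc,
    "varbvs": _varbvs,
    "mrash": _mrash,
    "tblup": _tblup,
    "go_tblup": _go_tblup,
}


def register_method(name: str, fn, overwrite: bool = False) -> None:
    """Add an external predictor to the registry (the plug-in interface)."""
    if name in REGISTRY and not overwrite:
        raise ValueError(f"method {name!r} already registered")
    REGISTRY[name] = fn


def get_methods(names: list[str]) -> dict:
    unknown = [n for n in names if n not in REGISTRY]
    if unknown:
        raise KeyError(f"unknown methods: {unknown}")
    return {n: REGISTRY[n] for n in names}
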