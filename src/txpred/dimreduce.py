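"""Principal-component and partial-least-squares regression.

Both methods replace the n x m expression matrix X by an n x k score matrix
T and regress the trait on the scores; k is chosen by 5-fold cross-validation
inside the training set, minimizing CV mean squared prediction error with
ties broken towards smaller k. k = 0 (intercept-only) is an admissible
winner and is flagged as a degenerate model.

PLSR uses the wide-kernel route: all score extraction happens on the n x n
cross-product matrix XX^T, which is the right shape for m >> n expression
data. The per-component eigen-step is iterative; exceeding ``max_iter``
records ``converged=False`` (a model failure for the evaluation protocol,
not an exception).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["ComponentModel", "fit_pcr", "fit_plsr", "cv_fold_indices"]

_RANK_TOL = 1e-10
# CV errors within this fraction of Var(y) of the minimum count as ties,
# broken toward smaller k (parsimony); real CV differences are far larger
_CV_TIE_TOL = 1e-8


def _select_k(cv_curve: np.ndarray, var_y: float) -> int:
    thresh = cv_curve.min() + _CV_TIE_TOL * max(var_y, 1e-300)
    return int(np.argmax(cv_curve <= thresh))


@dataclass
class ComponentModel:
    method: str
    k_selected: int
    cv_curve: np.ndarray  # CV MSE for k = 0 .. max_k
    x_mean: np.ndarray
    y_mean: float
    converged: bool = True
    intercept_only: bool = False
    # PCR: right-singular vectors + per-score coefficients
    loadings: np.ndarray | None = field(default=None, repr=False)
    score_coefs: np.ndarray | None = field(default=None, repr=False)
    # PLSR: training matrix + sample-space coefficient vector
    _train_X: np.ndarray | None = field(default=None, repr=False)
    _lambda: np.ndarray | None = field(default=None, repr=False)

    def predict(self, X_new: np.ndarray) -> np.ndarray:
        X_new = np.atleast_2d(np.asarray(X_new, float))
        if self.k_selected == 0:
            return np.full(X_new.shape[0], self.y_mean)
        Xc = X_new - self.x_mean
        if self.method == "pcr":
            scores = Xc @ self.loadings[:, : self.k_selected]
            return scores @ self.score_coefs[: self.k_selected] + self.y_mean
        K_cross = Xc @ self._train_X.T
        return K_cross @ self._lambda + self.y_mean


def cv_fold_indices(n: int, n_folds: int, seed: int) -> list[np.ndarray]:
    """Shuffle indices once under ``seed``, deal into contiguous blocks."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return [np.sort(block) for block in np.array_split(perm, n_folds)]


def _resolve_max_k(n: int, m: int, max_k: int | None) -> int:
    cap = min(n - 1, m)
    if max_k is None:
        return min(cap, 100)
    if max_k > cap:
        warnings.warn(f"max_k={max_k} clipped to min(n-1, m)={cap}")
        return cap
    return max_k


# ---------------------------------------------------------------------------
# PCR


def _pcr_components(Xc: np.ndarray, max_k: int):
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    rank = int(np.sum(s > _RANK_TOL * s[0])) if s.size else 0
    k = min(max_k, rank)
    return U[:, :k] * s[:k], Vt[:k].T, k  # scores, loadings


def _incremental_preds(scores_tr, y_tr, scores_val, kmax):
    """Validation predictions for k = 0..kmax using orthogonal training scores."""
    n_val = scores_val.shape[0]
    preds = np.zeros((kmax + 1, n_val))
    acc = np.zeros(n_val)
    for k in range(1, kmax + 1):
        t = scores_tr[:, k - 1]
        denom = t @ t
        coef = (t @ y_tr) / denom if denom > 0 else 0.0
        acc = acc + coef * scores_val[:, k - 1]
        preds[k] = acc
    return preds


def fit_pcr(
    X: np.ndarray,
    y: np.ndarray,
    max_k: int | None = None,
    cv_folds: int = 5,
    seed: int = 0,
) -> ComponentModel:
    """PCR with the component count selected by internal 5-fold CV.

    Components are the right-singular directions of the centered training
    matrix ordered by variance explained; at k = rank(X) the fit reproduces
    ordinary least squares on the training data.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    n, m = X.shape
    max_k = _resolve_max_k(n, m, max_k)
    x_mean = X.mean(axis=0)
    y_mean = y.mean()
    Xc, yc = X - x_mean, y - y_mean

    folds = cv_fold_indices(n, cv_folds, seed)
    sq_err = np.zeros(max_k + 1)
    for val_idx in folds:
        tr_mask = np.ones(n, bool)
        tr_mask[val_idx] = False
        Xtr, ytr = X[tr_mask], y[tr_mask]
        mu_x, mu_y = Xtr.mean(axis=0), ytr.mean()
        scores_tr, V, k_f = _pcr_components(Xtr - mu_x, max_k)
        scores_val = (X[val_idx] - mu_x) @ V
        preds = _incremental_preds(scores_tr, ytr - mu_y, scores_val, k_f) + mu_y
        if k_f < max_k:  # rank-deficient folds: constant error beyond k_f
            preds = np.vstack([preds, np.repeat(preds[-1:], max_k - k_f, axis=0)])
        sq_err += ((preds - y[val_idx]) ** 2).sum(axis=1)
    cv_curve = sq_err / n
    k_sel = _select_k(cv_curve, float(np.var(y)))

    scores, V, k_full = _pcr_components(Xc, max_k)
    k_sel = min(k_sel, k_full)
    denom = np.einsum("ij,ij->j", scores, scores)
    coefs = np.where(denom > 0, (scores.T @ yc) / np.where(denom > 0, denom, 1.0), 0.0)
    return ComponentModel(
        method="pcr",
        k_selected=k_sel,
        cv_curve=cv_curve,
        x_mean=x_mean,
        y_mean=y_mean,
        loadings=V,
        score_coefs=coefs,
        intercept_only=(k_sel == 0),
    )


# ---------------------------------------------------------------------------
# PLSR (wide-kernel)


def _widekernel_components(Xc, yc, max_k, max_iter, tol=1e-10):
    """Extract up to max_k PLS score vectors from the n x n kernel XX^T.

    Returns (T, U_tilde, q, converged): orthonormal scores, the deflated-y
    vectors defining the gene-space weights w_a = X^T u_a, the per-component
    regression coefficients q_a = t_a^T y, and the convergence flag of the
    iterative eigen-step.
    """
    n = Xc.shape[0]
    K = Xc @ Xc.T
    Kd = K.copy()
    yd = yc.copy()
    T, U, q = [], [], []
    converged = True
    for _ in range(max_k):
        v = Kd @ yd
        nv = np.linalg.norm(v)
        if nv < 1e-12 * max(1.0, np.linalg.norm(K)):
            break  # remaining kernel has no covariance with y
        # power iteration on the (rank-one) operator Kd yd yd^T
        t = yd / np.linalg.norm(yd)
        ok = False
        for _it in range(max_iter):
            t_new = Kd @ yd * (yd @ t)
            t_new /= np.linalg.norm(t_new)
            if np.linalg.norm(t_new - t) < tol or np.linalg.norm(t_new + t) < tol:
                t = t_new
                ok = True
                break
            t = t_new
        if not ok:
            converged = False
        U.append(yd.copy())
        T.append(t)
        q.append(t @ yc)
        # deflate: project the kernel and y off the extracted score
        Kt = Kd @ t
        Kd = Kd - np.outer(t, Kt) - np.outer(Kt, t) + (t @ Kt) * np.outer(t, t)
        yd = yd - t * (t @ yd)
    if not T:
        return (np.zeros((n, 0)), np.zeros((n, 0)), np.zeros(0), converged)
    return np.column_stack(T), np.column_stack(U), np.array(q), converged


def _plsr_lambda(K, T, U, q, k):
    """Sample-space coefficients: beta = X^T lambda, lambda = U_k (T_k^T K U_k)^-1 q_k."""
    A = T[:, :k].T @ K @ U[:, :k]
    return U[:, :k] @ np.linalg.solve(A, q[:k])


def fit_plsr(
    X: np.ndarray,
    y: np.ndarray,
    max_k: int | None = None,
    cv_folds: int = 5,
    max_iter: int = 100,
    seed: int = 0,
) -> ComponentModel:
    """Wide-kernel PLSR with CV-selected component count.

    The first latent weight vector is proportional to X^T y (covariance
    maximization); with k = rank(X) the training fit equals least squares.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    n, m = X.shape
    max_k = _resolve_max_k(n, m, max_k)
    x_mean = X.mean(axis=0)
    y_mean = y.mean()
    Xc, yc = X - x_mean, y - y_mean

    folds = cv_fold_indices(n, cv_folds, seed)
    sq_err = np.zeros(max_k + 1)
    converged = True
    for val_idx in folds:
        tr_mask = np.ones(n, bool)
        tr_mask[val_idx] = False
        Xtr, ytr = X[tr_mask], y[tr_mask]
        mu_x, mu_y = Xtr.mean(axis=0), ytr.mean()
        Xtr_c, ytr_c = Xtr - mu_x, ytr - mu_y
        T, U, qv, ok = _widekernel_components(Xtr_c, ytr_c, max_k, max_iter)
        converged &= ok
        K = Xtr_c @ Xtr_c.T
        K_cross = (X[val_idx] - mu_x) @ Xtr_c.T
        preds = np.zeros((max_k + 1, len(val_idx)))
        for k in range(1, T.shape[1] + 1):
            preds[k] = K_cross @ _plsr_lambda(K, T, U, qv, k)
        for k in range(T.shape[1] + 1, max_k + 1):
            preds[k] = preds[T.shape[1]]
        sq_err += ((preds + mu_y - y[val_idx]) ** 2).sum(axis=1)
    cv_curve = sq_err / n
    k_sel = _select_k(cv_curve, float(np.var(y)))

    T, U, qv, ok = _widekernel_components(Xc, yc, max_k, max_iter)
    converged &= ok
    k_sel = min(k_sel, T.shape[1])
    lam = _plsr_lambda(Xc @ Xc.T, T, U, qv, k_sel) if k_sel > 0 else None
    return ComponentModel(
        method="plsr",
        k_selected=k_sel,
        cv_curve=cv_curve,
        x_mean=x_mean,
        y_mean=y_mean,
        converged=converged,
        intercept_only=(k_sel == 0),
        _train_X=Xc,
        _lambda=lam,
    )
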