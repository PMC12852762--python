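"""Weighted maximum-likelihood solvers for the two model families the
pipeline fits thousands of times inside the bootstrap: binomial logistic
regression (the discrete-time pooled hazard and censoring models) and
multinomial softmax regression (the treatment propensity model).

Both use damped Newton iterations with an analytic gradient and Hessian and
converge by gradient norm < 1e-6 (at most 200 iterations).  The logistic
solver first collapses rows with identical design vectors into weighted
binomial counts, which makes a person-month fit on hundreds of thousands of
rows cost the same as one on a few hundred aggregated rows.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

__all__ = ["fit_weighted_logistic", "fit_softmax", "LogisticFit", "SoftmaxFit"]

_TOL = 1e-6
_MAX_ITER = 200


class ConvergenceError(RuntimeError):
    pass


class SeparationError(RuntimeError):
    """Perfect separation: the MLE does not exist for a named column."""


def _check_separation(beta: np.ndarray, columns) -> None:
    """A converged fit with an extreme coefficient means the likelihood is
    flat at the boundary: (quasi-)perfect separation."""
    b = np.atleast_2d(beta)
    if np.abs(b).max() > 15:
        j = int(np.abs(b).max(axis=0).argmax())
        col = columns[j] if columns else f"column {j}"
        raise SeparationError(
            f"perfect or quasi-perfect separation detected ({col})")


class LogisticFit:
    __slots__ = ("coef", "cov", "n_iter", "converged", "columns")

    def __init__(self, coef, cov, n_iter, converged, columns=None):
        self.coef = coef
        self.cov = cov
        self.n_iter = n_iter
        self.converged = converged
        self.columns = columns

    def predict(self, X: np.ndarray) -> np.ndarray:
        return expit(np.asarray(X, float) @ self.coef)


def _collapse(X: np.ndarray, y: np.ndarray, w: np.ndarray):
    """Aggregate identical design rows into (X_u, weighted events, weighted
    totals).  Valid because the weighted log-likelihood depends on the data
    only through these sums."""
    key = np.ascontiguousarray(X).view(
        np.dtype((np.void, X.dtype.itemsize * X.shape[1]))).ravel()
    order = np.argsort(key, kind="stable")
    key_s = key[order]
    boundaries = np.empty(len(key_s), bool)
    boundaries[0] = True
    boundaries[1:] = key_s[1:] != key_s[:-1]
    group = np.cumsum(boundaries) - 1
    Xu = X[order][boundaries]
    wy = np.bincount(group, weights=(w * y)[order])
    wt = np.bincount(group, weights=w[order])
    return Xu, wy, wt


def fit_weighted_logistic(X: np.ndarray, y: np.ndarray,
                          weights: np.ndarray | None = None,
                          columns: list[str] | None = None,
                          compress: bool = True) -> LogisticFit:
    """Weighted binomial logistic MLE of P(y=1 | X).

    ``weights`` scale each row's log-likelihood contribution (analysis
    weights, not frequency counts); the fitted coefficients are invariant to
    rescaling all weights by a constant.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    w = np.ones(len(y)) if weights is None else np.asarray(weights, float)
    if (w < 0).any():
        raise ValueError("weights must be non-negative")
    if compress:
        Xu, wy, wt = _collapse(X, y, w)
    else:
        Xu, wy, wt = X, w * y, w
    scale = wt.sum()
    beta = np.zeros(X.shape[1])
    for it in range(1, _MAX_ITER + 1):
        eta = Xu @ beta
        p = expit(eta)
        grad = Xu.T @ (wy - wt * p)
        v = wt * p * (1 - p)
        H = (Xu * v[:, None]).T @ Xu
        if np.linalg.norm(grad) / scale < _TOL:
            break
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        # dampen huge steps (quasi-separation safeguard)
        nrm = np.linalg.norm(step)
        if nrm > 20:
            step *= 20 / nrm
        beta = beta + step
        if np.abs(beta).max() > 40:
            col = columns[int(np.abs(beta).argmax())] if columns else \
                f"column {int(np.abs(beta).argmax())}"
            raise SeparationError(
                f"perfect or quasi-perfect separation detected ({col})")
    else:
        raise ConvergenceError("logistic fit did not converge in 200 iterations")
    _check_separation(beta, columns)
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(H)
    return LogisticFit(beta, cov, it, True, columns)


class SoftmaxFit:
    """Multinomial logistic fit with the first class as reference.

    ``coef`` has shape (K-1, p): log-odds of class k vs class 0 per design
    column.  ``cov`` is the observed-information covariance of the stacked
    coefficient vector (row-major over classes).
    """

    __slots__ = ("coef", "cov", "n_iter", "converged", "classes", "columns")

    def __init__(self, coef, cov, n_iter, converged, classes, columns=None):
        self.coef = coef
        self.cov = cov
        self.n_iter = n_iter
        self.converged = converged
        self.classes = classes
        self.columns = columns

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, float)
        eta = np.column_stack([np.zeros(len(X)), X @ self.coef.T])
        eta -= eta.max(axis=1, keepdims=True)
        p = np.exp(eta)
        p /= p.sum(axis=1, keepdims=True)
        return p

    def bse(self) -> np.ndarray:
        """Standard errors, shaped like ``coef``."""
        return np.sqrt(np.diag(self.cov)).reshape(self.coef.shape)


def fit_softmax(X: np.ndarray, y_idx: np.ndarray, n_classes: int,
                weights: np.ndarray | None = None,
                classes=None, columns: list[str] | None = None) -> SoftmaxFit:
    """Weighted multinomial (softmax) logistic MLE, reference class 0.

    ``y_idx`` holds class indices 0..K-1.  Newton-Raphson on the full
    block Hessian; gradient-norm convergence as in the binomial solver.
    """
    X = np.asarray(X, float)
    y_idx = np.asarray(y_idx, int)
    n, p = X.shape
    K = n_classes
    w = np.ones(n) if weights is None else np.asarray(weights, float)
    Y = np.zeros((n, K))
    Y[np.arange(n), y_idx] = 1.0
    beta = np.zeros((K - 1, p))
    scale = w.sum()
    for it in range(1, _MAX_ITER + 1):
        eta = np.column_stack([np.zeros(n), X @ beta.T])
        eta -= eta.max(axis=1, keepdims=True)
        P = np.exp(eta)
        P /= P.sum(axis=1, keepdims=True)
        R = (Y - P)[:, 1:] * w[:, None]          # n x (K-1)
        grad = (X.T @ R).T.ravel()               # stacked class-major
        H = np.empty(((K - 1) * p, (K - 1) * p))
        for a in range(1, K):
            for b in range(a, K):
                v = w * np.where(a == b, P[:, a] * (1 - P[:, a]),
                                 -P[:, a] * P[:, b])
                blk = (X * v[:, None]).T @ X
                H[(a - 1) * p:a * p, (b - 1) * p:b * p] = blk
                H[(b - 1) * p:b * p, (a - 1) * p:a * p] = blk
        if np.linalg.norm(grad) / scale < _TOL:
            break
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        nrm = np.linalg.norm(step)
        if nrm > 20:
            step *= 20 / nrm
        beta = beta + step.reshape(K - 1, p)
        if np.abs(beta).max() > 40:
            j = int(np.abs(beta).max(axis=0).argmax())
            col = columns[j] if columns else f"column {j}"
            raise SeparationError(
                f"perfect or quasi-perfect separation detected ({col})")
    else:
        raise ConvergenceError("softmax fit did not converge in 200 iterations")
    _check_separation(beta, columns)
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(H)
    return SoftmaxFit(beta, cov, it, True,
                      classes if classes is not None else np.arange(K), columns)
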