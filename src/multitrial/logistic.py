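"""Logistic-regression numerics: IRLS maximum likelihood with separation
detection, and a Firth (Jeffreys-prior) penalized fallback.

The resampling stages re-fit per-study models hundreds of thousands of
times, so this is a lean array-level implementation. Separation is flagged
when any coefficient exceeds ``coef_bound`` in absolute value along the
IRLS path or the deviance fails to decrease; flagged (or non-converged)
fits are re-run with Firth penalization, which has a finite maximum even
under complete separation, so resampling replicates always return a finite
statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import NonEstimableError

__all__ = ["LogisticFit", "fit_logistic"]

_MU_EPS = 1e-10


@dataclass
class LogisticFit:
    coef: np.ndarray
    cov: np.ndarray
    converged: bool
    penalized: bool
    separated: bool
    n_iter: int
    deviance: float


def _loglik(eta: np.ndarray, y: np.ndarray) -> float:
    # sum y*eta - log(1 + exp(eta)), stable for large |eta|
    return float(y @ eta - np.logaddexp(0.0, eta).sum())


def _solve(A: np.ndarray, b: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        return np.linalg.lstsq(A, b, rcond=None)[0]


def fit_logistic(X: np.ndarray, y: np.ndarray, max_iter: int = 100,
                 tol: float = 1e-8, coef_bound: float = 10.0,
                 allow_penalized: bool = True) -> LogisticFit:
    """Fit a binary logistic model by IRLS; fall back to Firth on separation.

    ``X`` must include an intercept column of ones first. The covariance is
    the inverse Fisher information at the final coefficients.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    ybar = y.mean()
    if ybar <= 0.0 or ybar >= 1.0:
        if not allow_penalized:
            raise NonEstimableError("outcome has a single level in this fit")
        return _fit_firth(X, y)

    # standard GLM initialization: start from mu near the data, not from a
    # constant-intercept fit (robust on small cells)
    mu = (y + 0.5) / 2.0
    eta = np.log(mu / (1.0 - mu))
    beta = np.zeros(p)
    dev_old = np.inf
    separated = False
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        w = mu * (1.0 - mu)
        z = eta + (y - mu) / w
        XtW = X.T * w
        beta_new = _solve(XtW @ X, XtW @ z)
        if not np.all(np.isfinite(beta_new)) or np.max(np.abs(beta_new)) > coef_bound:
            separated = True
            break
        dev = -2.0 * _loglik(X @ beta_new, y)
        if dev > dev_old + 1e-6 and it > 1:
            # step-halve toward the current iterate before giving up
            for _ in range(10):
                beta_new = 0.5 * (beta_new + beta)
                dev = -2.0 * _loglik(X @ beta_new, y)
                if dev <= dev_old + 1e-6:
                    break
            else:
                separated = True  # deviance failed to decrease along the path
                break
        beta = beta_new
        eta = X @ beta
        mu = np.clip(1.0 / (1.0 + np.exp(-eta)), _MU_EPS, 1.0 - _MU_EPS)
        if abs(dev_old - dev) < tol * (abs(dev) + 0.1):
            converged = True
            dev_old = dev
            break
        dev_old = dev

    if (separated or not converged) and allow_penalized:
        return _fit_firth(X, y)

    w = mu * (1.0 - mu)
    info = (X.T * w) @ X
    cov = _inv(info)
    return LogisticFit(coef=beta, cov=cov, converged=converged,
                       penalized=False, separated=separated, n_iter=it,
                       deviance=-2.0 * _loglik(eta, y))


def _inv(A: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.inv(A)
    except np.linalg.LinAlgError:
        return np.linalg.pinv(A)


def _fit_firth(X: np.ndarray, y: np.ndarray, max_iter: int = 200,
               tol: float = 1e-6) -> LogisticFit:
    """Firth-penalized logistic fit (Newton with step-halving).

    Maximizes l(b) + 0.5 log|I(b)|; the score adds h_i (0.5 - mu_i) to each
    residual, where h are the leverages of the weighted design.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    beta = np.zeros(p)

    def penalized_ll(b):
        eta = X @ b
        mu = np.clip(1.0 / (1.0 + np.exp(-eta)), _MU_EPS, 1.0 - _MU_EPS)
        info = (X.T * (mu * (1.0 - mu))) @ X
        sign, logdet = np.linalg.slogdet(info)
        if sign <= 0:
            return -np.inf
        return _loglik(eta, y) + 0.5 * logdet

    ll = penalized_ll(beta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = np.clip(1.0 / (1.0 + np.exp(-eta)), _MU_EPS, 1.0 - _MU_EPS)
        w = mu * (1.0 - mu)
        XtW = X.T * w
        info = XtW @ X
        info_inv = _inv(info)
        # leverages of W^{1/2} X
        h = np.einsum("ij,jk,ik->i", X, info_inv, X) * w
        score = X.T @ (y - mu + h * (0.5 - mu))
        delta = info_inv @ score
        # step-halving to guarantee ascent
        step = 1.0
        for _ in range(20):
            cand = beta + step * delta
            ll_new = penalized_ll(cand)
            if ll_new >= ll - 1e-12:
                break
            step *= 0.5
        else:
            cand, ll_new = beta, ll
        moved = np.max(np.abs(cand - beta))
        beta, ll = cand, ll_new
        if moved < tol:
            converged = True
            break

    eta = X @ beta
    mu = np.clip(1.0 / (1.0 + np.exp(-eta)), _MU_EPS, 1.0 - _MU_EPS)
    info = (X.T * (mu * (1.0 - mu))) @ X
    return LogisticFit(coef=beta, cov=_inv(info), converged=converged,
                       penalized=True, separated=True, n_iter=it,
                       deviance=-2.0 * _loglik(eta, y))
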