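"""Logistic-regression primitives: plain IRLS and Firth-penalized fits.

These are deliberately small and explicit — the association scan and the
propensity model both specify their iteration and convergence behaviour —
and are cross-checked in the test suite against an independent
maximum-likelihood oracle.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit


class SeparationError(RuntimeError):
    """The likelihood is monotone (perfect or quasi-perfect separation)."""


def _loglik(y, eta):
    # numerically safe Bernoulli log-likelihood
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def logistic_irls(X: np.ndarray, y: np.ndarray, max_iter: int = 100,
                  tol: float = 1e-8, beta0=None):
    """Maximum-likelihood logistic fit by Newton-Raphson (IRLS).

    Returns (beta, cov, n_iter, converged).  Raises
    :class:`SeparationError` when the fit diverges (coefficients blowing
    up without convergence), the classic symptom of separation.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    beta = np.zeros(p) if beta0 is None else np.array(beta0, dtype=float)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = expit(eta)
        w = mu * (1 - mu)
        XtW = X.T * w
        H = XtW @ X
        g = X.T @ (y - mu)
        try:
            step = np.linalg.solve(H + 1e-12 * np.eye(p), g)
        except np.linalg.LinAlgError:
            raise SeparationError(
                "singular information matrix (separated or collinear data; "
                "consider a Firth-penalized fit)")
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            converged = True
            break
        if np.max(np.abs(beta)) > 1e3:
            raise SeparationError(
                "coefficients diverging; data may be separated "
                "(consider a Firth-penalized fit)")
    if not converged:
        raise SeparationError(
            f"no convergence in {max_iter} IRLS iterations "
            "(consider a Firth-penalized fit)")
    eta = X @ beta
    mu = expit(eta)
    w = mu * (1 - mu)
    H = (X.T * w) @ X
    cov = np.linalg.inv(H + 1e-12 * np.eye(p))
    return beta, cov, it, converged


def firth_penalized_loglik(X, y, beta):
    eta = X @ beta
    mu = expit(eta)
    w = mu * (1 - mu)
    H = (X.T * w) @ X
    sign, logdet = np.linalg.slogdet(H)
    if sign <= 0:
        return -np.inf
    return _loglik(y, eta) + 0.5 * logdet


def firth_logistic(X: np.ndarray, y: np.ndarray, max_iter: int = 200,
                   tol: float = 1e-8):
    """Firth-penalized logistic fit (Jeffreys-prior penalty).

    Newton iterations on the modified score
    ``U*(beta) = X^T (y - mu + h (1/2 - mu))`` with ``h`` the hat-matrix
    diagonal, with step-halving on the penalized log-likelihood.

    Returns (beta, cov, pll, n_iter, converged).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    beta = np.zeros(p)
    pll = firth_penalized_loglik(X, y, beta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = expit(eta)
        w = np.clip(mu * (1 - mu), 1e-12, None)
        XtW = X.T * w
        H = XtW @ X
        try:
            Hinv = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            break
        # hat diagonal of W^1/2 X (X' W X)^-1 X' W^1/2
        h = np.einsum("ij,jk,ik->i", X * w[:, None], Hinv, X)
        U = X.T @ (y - mu + h * (0.5 - mu))
        step = Hinv @ U
        # step-halving to guarantee penalized-likelihood ascent
        new_pll = -np.inf
        for _ in range(25):
            cand = beta + step
            new_pll = firth_penalized_loglik(X, y, cand)
            if new_pll >= pll - 1e-10:
                break
            step = step / 2
        beta = beta + step
        moved = np.max(np.abs(step))
        pll = new_pll
        if moved < tol:
            converged = True
            break
    eta = X @ beta
    mu = expit(eta)
    w = np.clip(mu * (1 - mu), 1e-12, None)
    H = (X.T * w) @ X
    cov = np.linalg.inv(H)
    return beta, cov, pll, it, converged
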