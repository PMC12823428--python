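"""Fast Newton-Raphson fitting for logistic and linear models.

The association scans, the natural-effects mediation bootstrap and the
proteome-wide scan each fit thousands of small GLMs; this module provides a
compact IRLS implementation tuned for that workload.  It is cross-checked
against statsmodels in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

# Fitted probabilities closer to 0/1 than this suggest (quasi-)separation.
_SEP_PROB = 1e-8
_SEP_BETA = 25.0


@dataclass
class GlmFit:
    """Result of a single maximum-likelihood fit."""

    beta: np.ndarray
    se: np.ndarray
    cov: np.ndarray
    loglik: float
    converged: bool
    separated: bool
    n_iter: int

    @property
    def z(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.beta / self.se


def logistic_fit(
    X: np.ndarray,
    y: np.ndarray,
    weights: np.ndarray | None = None,
    offset: np.ndarray | None = None,
    max_iter: int = 60,
    tol: float = 1e-10,
) -> GlmFit:
    """Weighted maximum-likelihood logistic regression via Newton-Raphson.

    ``weights`` are prior (frequency/importance) weights, as used by the
    weighting-based natural-effects estimator; standard errors come from the
    observed information of the weighted log-likelihood.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    off = np.zeros(n) if offset is None else np.asarray(offset, dtype=float)

    beta = np.zeros(p)
    # intercept warm start if a constant column exists
    const = np.nonzero((X == X[0]).all(axis=0) & (X[0] != 0))[0]
    if const.size:
        ybar = np.clip(np.average(y, weights=w), 1e-6, 1 - 1e-6)
        beta[const[0]] = np.log(ybar / (1 - ybar)) / X[0, const[0]]

    ll_old = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta + off
        mu = _expit(eta)
        wt = w * mu * (1 - mu)
        grad = X.T @ (w * (y - mu))
        XtWX = (X * wt[:, None]).T @ X
        try:
            step = np.linalg.solve(XtWX, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(XtWX, grad, rcond=None)[0]
        # step-halving to guarantee likelihood ascent
        ll_new = -np.inf
        for half in range(25):
            cand = beta + step / (2.0**half)
            ll_new = _loglik(X, y, w, off, cand)
            if np.isfinite(ll_new) and ll_new >= ll_old - 1e-12:
                beta = cand
                break
        if abs(ll_new - ll_old) < tol * (abs(ll_old) + 1e-3):
            ll_old = ll_new
            converged = True
            break
        ll_old = ll_new

    eta = X @ beta + off
    mu = _expit(eta)
    wt = w * mu * (1 - mu)
    XtWX = (X * wt[:, None]).T @ X
    try:
        cov = np.linalg.inv(XtWX)
        se = np.sqrt(np.diag(cov))
    except np.linalg.LinAlgError:
        cov = np.full((p, p), np.nan)
        se = np.full(p, np.nan)

    separated = bool(
        np.any(np.abs(beta) > _SEP_BETA)
        or np.all((mu < _SEP_PROB) | (mu > 1 - _SEP_PROB))
        or not np.all(np.isfinite(se))
    )
    return GlmFit(beta, se, cov, float(ll_old), converged, separated, it)


def linear_fit(X: np.ndarray, y: np.ndarray) -> GlmFit:
    """OLS with classical (homoskedastic) standard errors."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    XtX = X.T @ X
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = max(n - p, 1)
    sigma2 = float(resid @ resid) / dof
    try:
        cov = sigma2 * np.linalg.inv(XtX)
        se = np.sqrt(np.diag(cov))
    except np.linalg.LinAlgError:
        cov = np.full((p, p), np.nan)
        se = np.full(p, np.nan)
    ll = -0.5 * n * (np.log(2 * np.pi * max(sigma2, 1e-300)) + 1)
    return GlmFit(beta, se, cov, ll, True, False, 1)


def _expit(eta: np.ndarray) -> np.ndarray:
    out = np.empty_like(eta)
    pos = eta >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-eta[pos]))
    e = np.exp(eta[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def _loglik(X, y, w, off, beta) -> float:
    eta = X @ beta + off
    # log(1+exp(eta)) computed stably
    lse = np.where(eta > 0, eta + np.log1p(np.exp(-np.abs(eta))), np.log1p(np.exp(eta)))
    return float(np.sum(w * (y * eta - lse)))
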