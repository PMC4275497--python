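"""Weighted proportional-odds (cumulative logit) regression.

Used for the single odds ratio an ordinal outcome gets in the benchmark
comparison: stack the survey and the benchmark microdata, regress the
ordinal response on the membership indicator, and report
exp(membership coefficient).  Supports probability weights with a
survey-style sandwich variance:  A^{-1} B A^{-1} with A the weighted
observed information and B = sum_i w_i^2 s_i s_i'.

Model: logit P(Y <= k | x) = alpha_k - x'beta, categories 1..K.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit


class ProportionalOddsError(RuntimeError):
    pass


@dataclass
class POFit:
    alphas: np.ndarray          # thresholds, strictly increasing
    beta: np.ndarray            # slope coefficients
    cov: np.ndarray             # sandwich covariance of (alphas, beta)
    loglik: float
    n: int

    def beta_se(self) -> np.ndarray:
        k = len(self.alphas)
        return np.sqrt(np.diag(self.cov)[k:])


def _prepare(y: np.ndarray, X: np.ndarray, weights):
    y = np.asarray(y)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.shape[0]:
        X = X.T
    cats = np.unique(y)
    if len(cats) < 2:
        raise ProportionalOddsError("response has fewer than 2 observed categories")
    # recode to 0..K-1 contiguous
    code = {c: i for i, c in enumerate(cats)}
    yc = np.vectorize(code.get)(y)
    w = np.ones(len(y)) if weights is None else np.asarray(weights, dtype=float)
    return yc, X, w, len(cats)


def _scores(params, yc, X, K):
    """Per-observation log-likelihood and score matrix (n x d), unweighted."""
    n, p = X.shape
    alphas = params[:K - 1]
    beta = params[K - 1:]
    eta = X @ beta
    a_hi = np.where(yc < K - 1, alphas[np.minimum(yc, K - 2)] - eta, np.inf)
    a_lo = np.where(yc > 0, alphas[np.maximum(yc - 1, 0)] - eta, -np.inf)
    F_hi = expit(a_hi)
    F_lo = expit(a_lo)
    prob = np.clip(F_hi - F_lo, 1e-300, None)
    ll = np.log(prob)

    f_hi = np.where(np.isfinite(a_hi), F_hi * (1 - F_hi), 0.0)
    f_lo = np.where(np.isfinite(a_lo), F_lo * (1 - F_lo), 0.0)
    S = np.zeros((n, K - 1 + p))
    rows = np.arange(n)
    hi_idx = np.minimum(yc, K - 2)
    lo_idx = np.maximum(yc - 1, 0)
    np.add.at(S, (rows[yc < K - 1], hi_idx[yc < K - 1]),
              (f_hi / prob)[yc < K - 1])
    np.add.at(S, (rows[yc > 0], lo_idx[yc > 0]), (-f_lo / prob)[yc > 0])
    S[:, K - 1:] = (((f_lo - f_hi) / prob))[:, None] * X
    return ll, S


def fit_proportional_odds(y, X, weights=None, tol: float = 1e-10) -> POFit:
    """Maximum (weighted) likelihood fit with sandwich covariance.

    Raises :class:`ProportionalOddsError` on nonconvergence or if the
    fitted thresholds are not strictly increasing.
    """
    yc, X, w, K = _prepare(y, X, weights)
    n, p = X.shape

    # start thresholds at pooled weighted empirical cumulative logits
    cum = np.array([(w * (yc <= k)).sum() for k in range(K - 1)]) / w.sum()
    cum = np.clip(cum, 1e-6, 1 - 1e-6)
    x0 = np.concatenate([np.log(cum / (1 - cum)), np.zeros(p)])

    def objective(params):
        ll, S = _scores(params, yc, X, K)
        return -(w @ ll), -(S * w[:, None]).sum(axis=0)

    res = minimize(objective, x0, jac=True, method="BFGS",
                   options={"gtol": 1e-9, "maxiter": 500})
    if not res.success and np.max(np.abs(res.jac)) > 1e-4 * max(1.0, w.sum() / n):
        raise ProportionalOddsError(f"optimizer failed: {res.message}")
    params = res.x
    alphas = params[:K - 1]
    if np.any(np.diff(alphas) <= 0):
        raise ProportionalOddsError("fitted thresholds not increasing")

    # observed information by central finite differences of the gradient
    d = len(params)
    A = np.zeros((d, d))
    eps = 1e-5 * np.maximum(1.0, np.abs(params))
    for j in range(d):
        up = params.copy(); up[j] += eps[j]
        dn = params.copy(); dn[j] -= eps[j]
        _, Su = _scores(up, yc, X, K)
        _, Sd = _scores(dn, yc, X, K)
        gu = (Su * w[:, None]).sum(axis=0)
        gd = (Sd * w[:, None]).sum(axis=0)
        A[:, j] = -(gu - gd) / (2 * eps[j])
    A = 0.5 * (A + A.T)

    _, S = _scores(params, yc, X, K)
    Sw = S * w[:, None]
    B = Sw.T @ Sw
    Ainv = np.linalg.inv(A)
    cov = Ainv @ B @ Ainv
    ll, _ = _scores(params, yc, X, K)
    return POFit(alphas=alphas, beta=params[K - 1:], cov=cov,
                 loglik=float(w @ ll), n=n)
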