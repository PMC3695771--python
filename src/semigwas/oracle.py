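"""Brute-force per-SNP reference fits, used only to verify the engines.

Everything here does the slow, obvious thing: build the augmented
design ``[X s]``, solve the textbook normal equations (or iterate
Fisher scoring with an explicit information-matrix inverse), one SNP at
a time.  These routines deliberately share no code with the
semi-parallel engines — they are the independent yardstick the engines
are tested against, and looping them over a genome is precisely the
cost the semi-parallel algebra removes.  Intended for test-scale
problems only (n up to a few thousand, m up to a few hundred).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


__all__ = ["OracleFit", "ols_per_snp", "logistic_ml_per_snp", "logistic_one_step_full"]


@dataclass
class OracleFit:
    """Full-design fit: coefficients ordered as (covariates..., SNP last)."""

    coefficients: np.ndarray
    se: np.ndarray
    converged: bool
    iterations: int
    loglik: float | None = None
    rss: float | None = None

    @property
    def snp_beta(self) -> float:
        return float(self.coefficients[-1])

    @property
    def snp_se(self) -> float:
        return float(self.se[-1])


def _augment(X: np.ndarray, s: np.ndarray | None) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1:
        X = X.T
    if s is None:
        return X
    return np.column_stack([X, np.asarray(s, dtype=float).ravel()])


def ols_per_snp(y: np.ndarray, X: np.ndarray, s: np.ndarray) -> OracleFit:
    """Textbook least squares on the augmented design [X s].

    Normal equations ``(A'A) b = A'y`` solved directly; the residual
    variance uses ``n - p`` degrees of freedom where p counts all
    columns of the augmented design (intercept + covariates + SNP).
    """
    y = np.asarray(y, dtype=float).ravel()
    A = _augment(X, s)
    n, p = A.shape
    if n <= p:
        raise ValueError(f"need n > {p} columns, got n={n}")
    ata = A.T @ A
    if np.linalg.matrix_rank(ata) < p:
        raise np.linalg.LinAlgError("augmented design [X s] is rank deficient")
    coef = np.linalg.solve(ata, A.T @ y)
    resid = y - A @ coef
    rss = float(resid @ resid)
    sigma2 = rss / (n - p)
    se = np.sqrt(sigma2 * np.diag(np.linalg.inv(ata)))
    return OracleFit(coefficients=coef, se=se, converged=True, iterations=1, rss=rss)


def _bernoulli_loglik(y: np.ndarray, eta: np.ndarray) -> float:
    # log L = sum y*eta - log(1 + exp(eta)), computed stably
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def logistic_ml_per_snp(
    y: np.ndarray,
    X: np.ndarray,
    s: np.ndarray | None = None,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> OracleFit:
    """Fully iterated Fisher scoring on [X s] with explicit information matrix.

    Newton steps are halved whenever the log-likelihood would decrease,
    so the deviance is non-increasing across iterations.  Standard
    errors come from the inverse information at convergence.
    """
    y = np.asarray(y, dtype=float).ravel()
    if np.unique(y).size < 2:
        raise ValueError("both classes must be present")
    A = _augment(X, s)
    n, p = A.shape
    beta = np.zeros(p)
    eta = A @ beta
    ll = _bernoulli_loglik(y, eta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        prob = 1.0 / (1.0 + np.exp(-eta))
        if np.any(prob < 1e-10) or np.any(prob > 1 - 1e-10):
            return OracleFit(
                coefficients=beta,
                se=np.full(p, np.nan),
                converged=False,
                iterations=it,
                loglik=ll,
            )
        w = prob * (1 - prob)
        info = (A * w[:, None]).T @ A
        score = A.T @ (y - prob)
        step = np.linalg.solve(info, score)
        # step halving: never accept a likelihood decrease
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            ll_cand = _bernoulli_loglik(y, A @ cand)
            if ll_cand >= ll - 1e-12:
                break
            scale /= 2.0
        beta = beta + scale * step
        eta = A @ beta
        ll_new = _bernoulli_loglik(y, eta)
        if np.max(np.abs(scale * step)) < tol:
            ll = ll_new
            converged = True
            break
        ll = ll_new
    prob = 1.0 / (1.0 + np.exp(-eta))
    w = prob * (1 - prob)
    info = (A * w[:, None]).T @ A
    se = np.sqrt(np.diag(np.linalg.inv(info)))
    return OracleFit(
        coefficients=beta, se=se, converged=converged, iterations=it, loglik=ll
    )


def logistic_one_step_full(
    y: np.ndarray,
    X: np.ndarray,
    s: np.ndarray,
    null_fit: OracleFit | np.ndarray,
) -> OracleFit:
    """Exactly one Fisher-scoring update of the full model from the null.

    The starting point is (null coefficients, 0): the converged
    covariate-only fit with the SNP coefficient at zero.  A single
    update solves ``(A'WA) b = A'W z`` with W and the working response z
    evaluated at the start — the quantity the semi-parallel projection
    algebra reproduces in block form.
    """
    y = np.asarray(y, dtype=float).ravel()
    A = _augment(X, s)
    gamma = (
        null_fit.coefficients if isinstance(null_fit, OracleFit) else np.asarray(null_fit)
    )
    start = np.concatenate([np.asarray(gamma, float).ravel(), [0.0]])
    eta = A @ start
    prob = 1.0 / (1.0 + np.exp(-eta))
    w = prob * (1 - prob)
    z = eta + (y - prob) / w
    info = (A * w[:, None]).T @ A
    beta = np.linalg.solve(info, (A * w[:, None]).T @ z)
    se = np.sqrt(np.diag(np.linalg.inv(info)))
    return OracleFit(
        coefficients=beta,
        se=se,
        converged=True,
        iterations=1,
        loglik=_bernoulli_loglik(y, A @ beta),
    )
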