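"""Weighted logistic regression with sandwich (robust) variance.

Shared backbone for the bivariable odds-ratio grid and the post-selection
network refits.  The fit maximises the weight-scaled Bernoulli log-likelihood
by Newton-Raphson; the covariance is the usual A^{-1} B A^{-1} sandwich with

    A = X' diag(w mu (1-mu)) X       (weighted Fisher information)
    B = X' diag(w^2 (y-mu)^2) X      (outer product of weighted scores)

No small-sample degrees-of-freedom factor is applied, so under equal weights
the sandwich collapses exactly onto the model-based covariance for saturated
binary designs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_MAX_ABS_COEF = 30.0


class SeparationError(RuntimeError):
    """Raised when the weighted likelihood has no finite maximiser."""


@dataclass
class LogitFit:
    coef: np.ndarray          # includes intercept as coef[0]
    cov_sandwich: np.ndarray
    cov_model: np.ndarray
    n_iter: int
    converged: bool

    def se(self, robust: bool = True) -> np.ndarray:
        cov = self.cov_sandwich if robust else self.cov_model
        return np.sqrt(np.diag(cov))


def fit_weighted_logit(
    X: np.ndarray,
    y: np.ndarray,
    weights: np.ndarray | None = None,
    *,
    add_intercept: bool = True,
    max_iter: int = 100,
    tol: float = 1e-12,
) -> LogitFit:
    """Newton-Raphson fit of a weighted logistic regression.

    Parameters
    ----------
    X : (n, k) design matrix (without intercept unless add_intercept=False).
    y : (n,) binary outcome.
    weights : positive observation weights; defaults to 1.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if (w <= 0).any():
        raise ValueError("weights must be strictly positive")
    if add_intercept:
        X = np.column_stack([np.ones(n), X])
    k = X.shape[1]

    beta = np.zeros(k)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        v = w * mu * (1.0 - mu)
        score = X.T @ (w * (y - mu))
        info = (X * v[:, None]).T @ X
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError as exc:
            raise SeparationError("singular information matrix") from exc
        beta_new = beta + step
        if np.abs(beta_new).max() > _MAX_ABS_COEF:
            raise SeparationError(
                "coefficients diverging; data are (quasi-)separated"
            )
        if np.abs(step).max() < tol:
            beta = beta_new
            converged = True
            break
        beta = beta_new
    if not converged:
        # Accept near-stationary points; otherwise report failure.
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        if np.abs(X.T @ (w * (y - mu))).max() > 1e-6 * max(1.0, w.sum()):
            raise SeparationError("Newton-Raphson failed to converge")

    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    v = w * mu * (1.0 - mu)
    A = (X * v[:, None]).T @ X
    resid = w * (y - mu)
    B = (X * (resid**2)[:, None]).T @ X
    A_inv = np.linalg.inv(A)
    cov_sandwich = A_inv @ B @ A_inv
    return LogitFit(
        coef=beta,
        cov_sandwich=cov_sandwich,
        cov_model=A_inv,
        n_iter=it,
        converged=True,
    )
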