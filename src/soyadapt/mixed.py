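"""Single-random-effect mixed model via eigendecomposition REML.

Model: y = X b + g + e with g ~ N(0, sigma_a^2 K) and e ~ N(0, sigma_e^2 I).
Eigendecomposing K once reduces the restricted likelihood to a one-dimensional
profile over the variance ratio lambda = sigma_a^2 / sigma_e^2, optimized by
golden-section search on log-lambda.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = ["VarianceComponents", "fit_reml", "reml_loglik_null"]

_LOG_LAMBDA_BOUNDS = (-10.0, 10.0)


@dataclass
class VarianceComponents:
    sigma2_a: float
    sigma2_e: float
    h2: float
    loglik: float
    converged: bool
    boundary: bool = False

    def __post_init__(self) -> None:
        if self.sigma2_a < 0 or self.sigma2_e < 0:
            raise ValueError("variance components must be nonnegative")


def _profile(log_lam: float, s: np.ndarray, ystar: np.ndarray, xstar: np.ndarray) -> tuple:
    """Profiled REML negative log-likelihood at a given log variance ratio."""
    lam = np.exp(log_lam)
    d = lam * s + 1.0
    n, p = xstar.shape
    xd = xstar / d[:, None]
    xtx = xstar.T @ xd
    xty = xd.T @ ystar
    beta = np.linalg.solve(xtx, xty)
    r = ystar - xstar @ beta
    quad = float(r @ (r / d))
    df = n - p
    sigma2_e = quad / df
    sign, logdet_x = np.linalg.slogdet(xtx)
    if sign <= 0:
        return np.inf, sigma2_e, beta
    ll = -0.5 * (
        df * np.log(sigma2_e)
        + np.sum(np.log(d))
        + logdet_x
        + df * (1.0 + np.log(2.0 * np.pi))
    )
    return -ll, sigma2_e, beta


def fit_reml(
    y: np.ndarray,
    K: np.ndarray | None = None,
    X: np.ndarray | None = None,
    eig: tuple | None = None,
) -> VarianceComponents:
    """REML fit; ``eig`` may carry a precomputed (eigenvalues, eigenvectors).

    With ``K`` (and ``eig``) absent the model collapses to ordinary least
    squares and sigma2_a = 0 is returned with the corresponding restricted
    likelihood, which makes likelihoods comparable across kinship choices.
    """
    y = np.asarray(y, float)
    n = y.size
    if X is None:
        X = np.ones((n, 1))
    X = np.asarray(X, float)
    if X.ndim == 1:
        X = X[:, None]

    if K is None and eig is None:
        # pure fixed-effects REML: zero eigenvalues make lambda irrelevant
        neg_ll, sigma2_e, _ = _profile(0.0, np.zeros(n), y, X)
        return VarianceComponents(
            sigma2_a=0.0, sigma2_e=sigma2_e, h2=0.0, loglik=-neg_ll, converged=True
        )

    if eig is None:
        vals, vecs = np.linalg.eigh((K + K.T) / 2.0)
    else:
        vals, vecs = eig
    vals = np.maximum(vals, 0.0)
    ystar = vecs.T @ y
    xstar = vecs.T @ X

    res = minimize_scalar(
        lambda t: _profile(t, vals, ystar, xstar)[0],
        bounds=_LOG_LAMBDA_BOUNDS,
        method="bounded",
        options={"xatol": 1e-6},
    )
    log_lam = float(res.x)
    neg_ll, sigma2_e, _ = _profile(log_lam, vals, ystar, xstar)
    lam = np.exp(log_lam)
    sigma2_a = lam * sigma2_e
    h2 = sigma2_a / (sigma2_a + sigma2_e)
    boundary = (
        log_lam <= _LOG_LAMBDA_BOUNDS[0] + 1e-3 or log_lam >= _LOG_LAMBDA_BOUNDS[1] - 1e-3
    )
    if boundary:
        warnings.warn("REML variance ratio at optimization boundary")
    return VarianceComponents(
        sigma2_a=float(sigma2_a),
        sigma2_e=float(sigma2_e),
        h2=float(h2),
        loglik=float(-neg_ll),
        converged=bool(res.success),
        boundary=boundary,
    )


def reml_loglik_null(y: np.ndarray, X: np.ndarray | None = None) -> float:
    """Restricted log-likelihood of the fixed-effects-only model."""
    y = np.asarray(y, float)
    n = y.size
    if X is None:
        X = np.ones((n, 1))
    X = np.asarray(X, float)
    if X.ndim == 1:
        X = X[:, None]
    neg_ll, _, _ = _profile(_LOG_LAMBDA_BOUNDS[0], np.zeros(n), y, X)
    return -neg_ll
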