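"""Zero-mean Gaussian-process regression and the Expected-Improvement selector.

The GP prior has mean zero and squared-exponential covariance

    cov[f(x), f(x')] = exp(-theta ||x - x'||^2) + delta(x, x') sigma_n,

with the kernel scale theta and the additive noise term sigma_n selected
by maximizing the log marginal likelihood over a small grid.  The prior
amplitude is fixed at 1, so targets are standardized before fitting and
posterior moments are destandardized for reporting.

Expected Improvement for minimization, with mu* the best measurement so
far and posterior moments mu(x), sigma(x):

    E(x) = (mu* - mu) Phi((mu* - mu)/sigma) + sigma phi((mu* - mu)/sigma),

with the sigma -> 0 limit E = max(mu* - mu, 0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg
from scipy.spatial.distance import cdist
from scipy.stats import norm

__all__ = [
    "GPModel",
    "gp_fit",
    "gp_predict",
    "expected_improvement",
    "candidate_probability",
    "DEFAULT_THETA_GRID",
    "DEFAULT_NOISE_GRID",
]

DEFAULT_THETA_GRID: tuple[float, ...] = (0.01, 0.03, 0.1, 0.3, 1.0, 3.0)
DEFAULT_NOISE_GRID: tuple[float, ...] = (1e-6, 1e-4, 1e-2, 1e-1)


@dataclass
class GPModel:
    """Fitted GP: cached Cholesky factor and dual coefficients."""

    X_train: np.ndarray
    theta: float
    sigma_n: float
    y_mean: float
    y_scale: float
    chol: np.ndarray          # lower Cholesky factor of K + jitter
    alpha: np.ndarray         # (K)^-1 z for standardized targets z
    log_marginal_likelihood: float


def _sq_kernel(X: np.ndarray, Y: np.ndarray, theta: float) -> np.ndarray:
    return np.exp(-theta * cdist(X, Y, "sqeuclidean"))


def _try_factor(K: np.ndarray) -> np.ndarray | None:
    for jitter in (0.0, 1e-12, 1e-10, 1e-8):
        try:
            return linalg.cholesky(K + jitter * np.eye(K.shape[0]), lower=True)
        except linalg.LinAlgError:
            continue
    return None


def gp_fit(
    X: np.ndarray,
    y: np.ndarray,
    theta_grid: tuple[float, ...] = DEFAULT_THETA_GRID,
    noise_grid: tuple[float, ...] = DEFAULT_NOISE_GRID,
    standardize_y: bool = True,
) -> GPModel:
    """Select (theta, sigma_n) by grid-maximized log marginal likelihood.

    Ties break toward smaller theta, then smaller sigma_n.  ``X`` must be
    standardized features.  With ``standardize_y`` the targets are
    centred/scaled internally so the unit prior amplitude is appropriate.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    if n < 1:
        raise ValueError("need at least one training point")
    if standardize_y:
        y_mean = float(y.mean())
        y_scale = float(y.std())
        if y_scale == 0:
            y_scale = 1.0
    else:
        y_mean, y_scale = 0.0, 1.0
    z = (y - y_mean) / y_scale

    best: GPModel | None = None
    d2 = cdist(X, X, "sqeuclidean")
    for theta in sorted(theta_grid):
        base = np.exp(-theta * d2)
        for sigma_n in sorted(noise_grid):
            K = base + sigma_n * np.eye(n)
            L = _try_factor(K)
            if L is None:
                continue
            alpha = linalg.cho_solve((L, True), z)
            lml = (-0.5 * z @ alpha
                   - np.log(np.diag(L)).sum()
                   - 0.5 * n * np.log(2.0 * np.pi))
            if best is None or lml > best.log_marginal_likelihood + 1e-12:
                best = GPModel(
                    X_train=X.copy(), theta=theta, sigma_n=sigma_n,
                    y_mean=y_mean, y_scale=y_scale, chol=L, alpha=alpha,
                    log_marginal_likelihood=float(lml),
                )
    if best is None:
        raise np.linalg.LinAlgError(
            "covariance matrix not positive definite for any grid point"
        )
    return best


def gp_predict(model: GPModel, X_new: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Posterior mean and standard deviation of the latent response.

    Far from the data the mean decays to the prior mean (the training
    average after destandardization) and the standard deviation rises to
    the prior level.
    """
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != model.X_train.shape[1]:
        raise ValueError(
            f"dimension mismatch: {X_new.shape[1]} vs "
            f"{model.X_train.shape[1]} features"
        )
    k_star = _sq_kernel(X_new, model.X_train, model.theta)
    mu_z = k_star @ model.alpha
    v = linalg.solve_triangular(model.chol, k_star.T, lower=True)
    var_z = np.clip(1.0 - np.einsum("ij,ij->j", v, v), 0.0, None)
    mu = mu_z * model.y_scale + model.y_mean
    sd = np.sqrt(var_z) * model.y_scale
    return mu, sd


def expected_improvement(
    mu_star: float, mu: np.ndarray | float, sigma: np.ndarray | float
) -> np.ndarray | float:
    """EI for minimization; exact sigma=0 limit max(mu* - mu, 0)."""
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    scalar = mu.ndim == 0 and sigma.ndim == 0
    mu, sigma = np.broadcast_arrays(np.atleast_1d(mu), np.atleast_1d(sigma))
    if np.any(sigma < 0):
        raise ValueError("sigma must be non-negative")
    improvement = mu_star - mu
    ei = np.maximum(improvement, 0.0)
    pos = sigma > 0
    if pos.any():
        z = improvement[pos] / sigma[pos]
        ei_pos = improvement[pos] * norm.cdf(z) + sigma[pos] * norm.pdf(z)
        ei = ei.copy()
        ei[pos] = np.maximum(ei_pos, 0.0)
    return float(ei[0]) if scalar else ei


def candidate_probability(
    mu: np.ndarray | float,
    sigma: np.ndarray | float,
    target: float,
    tolerance: float,
) -> np.ndarray | float:
    """Posterior probability that the response lies within target +- tolerance.

    Gaussian mass Phi((t + tol - mu)/sigma) - Phi((t - tol - mu)/sigma);
    for sigma = 0 it degenerates to the indicator |mu - target| <= tol.
    """
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    scalar = mu.ndim == 0
    mu, sigma = np.atleast_1d(mu), np.atleast_1d(np.broadcast_to(sigma, mu.shape))
    prob = np.where(np.abs(mu - target) <= tolerance, 1.0, 0.0)
    pos = sigma > 0
    if pos.any():
        hi = norm.cdf((target + tolerance - mu[pos]) / sigma[pos])
        lo = norm.cdf((target - tolerance - mu[pos]) / sigma[pos])
        prob = prob.copy()
        prob[pos] = hi - lo
    return float(prob[0]) if scalar else prob
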