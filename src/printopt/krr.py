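"""Kernel ridge regression with a polynomial kernel, written from scratch.

The surrogate maps standardized processing parameters to defect
fractions.  With kernel matrix K over the n training points, the dual
weights solve the ridge system

    w = (K + lambda I)^{-1} y,

and a prediction at x* is  yhat = sum_i w_i K(x_i, x*).  The training
loss being minimized is  sum_i (yhat_i - y_i)^2 + lambda w^T K w.  The
kernel is polynomial,  K(x, x') = (gamma <x, x'> + c)^d,  with degree 3
and additive coefficient 0.2 by default; gamma defaults to 1/n_features.
Hyperparameters are selected by 10-fold cross-validated grid search.
Regularization strength: 0.5 (batch printer profile) or 0.7 (continuous).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import linalg

__all__ = [
    "KernelConfig",
    "KRRModel",
    "MetricsReport",
    "polynomial_kernel",
    "krr_fit",
    "krr_predict",
    "krr_loss",
    "grid_search_cv",
    "compute_metrics",
]


@dataclass(frozen=True)
class KernelConfig:
    """Polynomial kernel (gamma <x, x'> + coef0)^degree."""

    degree: int = 3
    coef0: float = 0.2
    gamma: float | None = None  # None -> 1 / n_features at call time

    def __post_init__(self) -> None:
        if self.degree < 1 or int(self.degree) != self.degree:
            raise ValueError("degree must be a positive integer")
        if self.coef0 < 0:
            raise ValueError("coef0 must be >= 0")
        if self.gamma is not None and self.gamma <= 0:
            raise ValueError("gamma must be > 0")

    def effective_gamma(self, n_features: int) -> float:
        return self.gamma if self.gamma is not None else 1.0 / n_features


def polynomial_kernel(
    X: np.ndarray, Y: np.ndarray | None = None, config: KernelConfig | None = None
) -> np.ndarray:
    """Kernel matrix K[i, j] = (gamma <X_i, Y_j> + c)^d.

    Accepts single vectors or row matrices; the matrix over any finite
    point set is positive semidefinite.
    """
    config = config or KernelConfig()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = X if Y is None else np.atleast_2d(np.asarray(Y, dtype=float))
    if X.shape[1] != Y.shape[1]:
        raise ValueError(
            f"dimension mismatch: {X.shape[1]} vs {Y.shape[1]} features"
        )
    gamma = config.effective_gamma(X.shape[1])
    K = (gamma * (X @ Y.T) + config.coef0) ** config.degree
    return K


@dataclass
class KRRModel:
    """Fitted kernel ridge model (dual weights over the training set)."""

    X_train: np.ndarray
    weights: np.ndarray
    lam: float
    kernel: KernelConfig

    @property
    def n_train(self) -> int:
        return self.X_train.shape[0]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "X_train": self.X_train.tolist(),
            "weights": self.weights.tolist(),
            "lambda": self.lam,
            "kernel": {"degree": self.kernel.degree, "coef0": self.kernel.coef0,
                       "gamma": self.kernel.gamma},
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "KRRModel":
        payload = json.loads(Path(path).read_text())
        return cls(
            X_train=np.array(payload["X_train"], dtype=float),
            weights=np.array(payload["weights"], dtype=float),
            lam=payload["lambda"],
            kernel=KernelConfig(**payload["kernel"]),
        )


def krr_fit(
    X: np.ndarray, y: np.ndarray, lam: float, config: KernelConfig | None = None
) -> KRRModel:
    """Solve (K + lambda I) w = y by Cholesky with jitter escalation.

    Never forms an explicit inverse.  ``X`` must already be standardized.
    """
    config = config or KernelConfig()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if lam <= 0:
        raise ValueError("regularization strength lambda must be > 0")
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y row counts differ")
    K = polynomial_kernel(X, X, config)
    A = K + lam * np.eye(X.shape[0])
    weights = None
    for jitter in (0.0, 1e-10, 1e-8, 1e-6):
        try:
            c, low = linalg.cho_factor(A + jitter * np.eye(X.shape[0]))
            weights = linalg.cho_solve((c, low), y)
            break
        except linalg.LinAlgError:
            continue
    if weights is None:
        raise np.linalg.LinAlgError(
            "kernel system not positive definite even after jitter 1e-6"
        )
    return KRRModel(X_train=X.copy(), weights=weights, lam=lam, kernel=config)


def krr_predict(model: KRRModel, X_new: np.ndarray) -> np.ndarray:
    """yhat_j = sum_i w_i K(x_i, x_j) on already-standardized inputs."""
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    K_cross = polynomial_kernel(X_new, model.X_train, model.kernel)
    return K_cross @ model.weights


def krr_loss(model: KRRModel, X: np.ndarray, y: np.ndarray) -> float:
    """Squared-error data term plus the lambda w^T K w ridge penalty."""
    y = np.asarray(y, dtype=float).ravel()
    resid = krr_predict(model, X) - y
    K = polynomial_kernel(model.X_train, model.X_train, model.kernel)
    penalty = model.weights @ K @ model.weights
    return float(resid @ resid + model.lam * penalty)


def _fold_indices(n: int, folds: int, rng: np.random.Generator) -> list[np.ndarray]:
    perm = rng.permutation(n)
    return [np.sort(chunk) for chunk in np.array_split(perm, folds)]


def grid_search_cv(
    X: np.ndarray,
    y: np.ndarray,
    lam_grid: tuple[float, ...] = (0.01, 0.05, 0.1, 0.3, 0.5, 0.7, 1.0),
    kernel_grid: tuple[KernelConfig, ...] = (KernelConfig(),),
    folds: int = 10,
    seed: int | None = 0,
) -> tuple[float, KernelConfig, pd.DataFrame]:
    """10-fold cross-validated grid search over (lambda, kernel).

    Returns the (lambda, kernel) pair minimizing mean validation MSE and
    the full CV table.  Ties break toward the smallest lambda, then the
    lowest kernel grid index.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    if n < folds:
        raise ValueError(f"need at least {folds} samples for {folds}-fold CV, got {n}")
    rng = np.random.default_rng(seed)
    fold_idx = _fold_indices(n, folds, rng)
    rows = []
    for ki, kernel in enumerate(kernel_grid):
        for lam in lam_grid:
            fold_mse = []
            for val in fold_idx:
                mask = np.ones(n, dtype=bool)
                mask[val] = False
                model = krr_fit(X[mask], y[mask], lam, kernel)
                resid = krr_predict(model, X[val]) - y[val]
                fold_mse.append(float(np.mean(resid**2)))
            rows.append({
                "kernel_index": ki, "degree": kernel.degree, "coef0": kernel.coef0,
                "gamma": kernel.gamma, "lambda": lam,
                "mean_mse": float(np.mean(fold_mse)),
            })
    table = pd.DataFrame(rows)
    # stable argmin with the documented tie-break order
    order = table.sort_values(
        ["mean_mse", "lambda", "kernel_index"], kind="mergesort"
    )
    best = order.iloc[0]
    return float(best["lambda"]), kernel_grid[int(best["kernel_index"])], table


@dataclass(frozen=True)
class MetricsReport:
    """R^2, MAE and RMSE of predictions against held-out measurements."""

    r2: float
    mae: float
    rmse: float
    n: int

    def as_dict(self) -> dict[str, float]:
        return {"r2": self.r2, "mae": self.mae, "rmse": self.rmse, "n": self.n}


def compute_metrics(y: np.ndarray, y_pred: np.ndarray) -> MetricsReport:
    """R^2 = 1 - SSE/SST, MAE = mean |e|, RMSE = sqrt(mean e^2)."""
    y = np.asarray(y, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y.shape != y_pred.shape:
        raise ValueError("y and y_pred lengths differ")
    if y.size < 2:
        raise ValueError("need at least 2 samples")
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0:
        raise ValueError("R^2 undefined: zero variance in y")
    err = y_pred - y
    return MetricsReport(
        r2=1.0 - float(np.sum(err**2)) / sst,
        mae=float(np.mean(np.abs(err))),
        rmse=float(np.sqrt(np.mean(err**2))),
        n=y.size,
    )
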