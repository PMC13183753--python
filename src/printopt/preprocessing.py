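"""Standardization and train/test splitting for the defect datasets.

Features are standardized per column, x_new = (x - mu) / sigma, with the
population (divisor n) standard deviation; the test set is always scaled
with the training set's mu and sigma.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .dataset import FEATURE_NAMES, DefectDataset

__all__ = ["ScalingState", "fit_scaler", "apply_scaler", "invert_scaler",
           "split_dataset"]


@dataclass(frozen=True)
class ScalingState:
    """Per-feature mean and population standard deviation."""

    mean: np.ndarray
    std: np.ndarray
    feature_names: tuple[str, ...] = FEATURE_NAMES

    def to_json(self, path: str | Path) -> None:
        payload = {
            "mean": list(self.mean),
            "std": list(self.std),
            "feature_names": list(self.feature_names),
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "ScalingState":
        payload = json.loads(Path(path).read_text())
        return cls(
            mean=np.array(payload["mean"], dtype=float),
            std=np.array(payload["std"], dtype=float),
            feature_names=tuple(payload["feature_names"]),
        )


def fit_scaler(
    X: np.ndarray,
    feature_names: tuple[str, ...] = FEATURE_NAMES,
    allow_constant: bool = False,
) -> ScalingState:
    """Learn column means and population standard deviations.

    A constant column is an error (its sigma would be zero) unless
    ``allow_constant`` is set, in which case its sigma is forced to 1 so
    the column passes through centred but unscaled.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 rows")
    mean = X.mean(axis=0)
    std = X.std(axis=0)  # numpy default ddof=0: population form
    zero = std == 0
    if zero.any():
        if not allow_constant:
            names = [feature_names[j] if j < len(feature_names) else str(j)
                     for j in np.flatnonzero(zero)]
            raise ValueError(f"constant feature(s) cannot be standardized: {names}")
        std = np.where(zero, 1.0, std)
    return ScalingState(mean=mean, std=std, feature_names=tuple(feature_names))


def apply_scaler(state: ScalingState, X: np.ndarray) -> np.ndarray:
    """Standardize rows with the training-set mean and sigma."""
    X = np.asarray(X, dtype=float)
    single = X.ndim == 1
    if single:
        X = X.reshape(1, -1)
    if X.shape[1] != state.mean.shape[0]:
        raise ValueError(
            f"feature count mismatch: data has {X.shape[1]}, "
            f"scaler was fit on {state.mean.shape[0]}"
        )
    out = (X - state.mean) / state.std
    return out[0] if single else out


def invert_scaler(state: ScalingState, X_scaled: np.ndarray) -> np.ndarray:
    """Map standardized values back to original units."""
    X_scaled = np.asarray(X_scaled, dtype=float)
    return X_scaled * state.std + state.mean


def split_dataset(
    dataset: DefectDataset,
    test_share: float = 0.20,
    seed: int | np.random.Generator | None = None,
) -> tuple[DefectDataset, DefectDataset]:
    """Uniformly random 80:20 row-level partition into (train, test).

    Test size is round(n * test_share); train and test are disjoint and
    together cover the dataset.  Replicates of one combination may land on
    both sides (row-level split).
    """
    n = len(dataset)
    if n < 5:
        raise ValueError("need at least 5 rows to split")
    if not 0.0 < test_share < 1.0:
        raise ValueError("test_share must lie in (0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_test = int(round(n * test_share))
    perm = rng.permutation(n)
    test_idx = np.sort(perm[:n_test])
    train_idx = np.sort(perm[n_test:])
    return dataset.subset(train_idx), dataset.subset(test_idx)
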