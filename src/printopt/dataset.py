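"""Tabular container for print-parameter / defect measurements.

A :class:`DefectDataset` is the ML training table of the pipeline: one row
per printed replicate, four processing features (print speed, infill
density, print temperature, flow rate) and the measured surface-defect
fraction of that replicate.  Defects are carried as fractions in [0, 1]
throughout; percent is a presentation concern only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: canonical feature order used everywhere in the package
FEATURE_NAMES: tuple[str, ...] = (
    "print_speed",
    "infill_density",
    "print_temperature",
    "flow_rate",
)

#: CSV schema for measurement tables
CSV_COLUMNS: tuple[str, ...] = FEATURE_NAMES + ("replicate", "defect_fraction")


@dataclass
class DefectDataset:
    """Feature matrix plus per-replicate defect fractions.

    Parameters
    ----------
    X : ndarray of shape (n, 4)
        Processing parameters, columns in :data:`FEATURE_NAMES` order
        (mm/s, %, degC, mm^3/s).
    y : ndarray of shape (n,)
        Measured defect fractions in [0, 1].
    combination_index : ndarray of shape (n,), optional
        Index of the source parameter combination for each replicate row.
    replicate : ndarray of shape (n,), optional
        Replicate number within each combination (0-based).
    """

    X: np.ndarray
    y: np.ndarray
    combination_index: np.ndarray | None = None
    replicate: np.ndarray | None = None
    feature_names: tuple[str, ...] = FEATURE_NAMES

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be a 2-D array")
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError(
                f"X has {self.X.shape[0]} rows but y has {self.y.shape[0]}"
            )
        if self.X.shape[1] != len(self.feature_names):
            raise ValueError(
                f"X has {self.X.shape[1]} columns, expected {len(self.feature_names)}"
            )
        if not np.all(np.isfinite(self.X)) or not np.all(np.isfinite(self.y)):
            raise ValueError("dataset contains non-finite values")
        if np.any(self.y < 0) or np.any(self.y > 1):
            raise ValueError("defect fractions must lie in [0, 1]")
        for name, attr in (("combination_index", self.combination_index),
                           ("replicate", self.replicate)):
            if attr is not None:
                arr = np.asarray(attr)
                if arr.shape[0] != self.X.shape[0]:
                    raise ValueError(f"{name} length does not match X")
                setattr(self, name, arr)

    def __len__(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def subset(self, idx: np.ndarray) -> "DefectDataset":
        """Row-indexed view (copy) of the dataset."""
        idx = np.asarray(idx)
        return DefectDataset(
            X=self.X[idx],
            y=self.y[idx],
            combination_index=None if self.combination_index is None
            else self.combination_index[idx],
            replicate=None if self.replicate is None else self.replicate[idx],
            feature_names=self.feature_names,
        )

    def append_row(self, x: np.ndarray, y: float,
                   combination_index: int | None = None) -> "DefectDataset":
        """Return a new dataset with one extra measured row."""
        x = np.asarray(x, dtype=float).reshape(1, -1)
        comb = self.combination_index
        if comb is not None:
            new_idx = comb.max() + 1 if combination_index is None else combination_index
            comb = np.concatenate([comb, [new_idx]])
        rep = self.replicate
        if rep is not None:
            rep = np.concatenate([rep, [0]])
        return DefectDataset(
            X=np.vstack([self.X, x]),
            y=np.concatenate([self.y, [float(y)]]),
            combination_index=comb,
            replicate=rep,
            feature_names=self.feature_names,
        )

    # ------------------------------------------------------------------
    # I/O
    # ------------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.X, columns=list(self.feature_names))
        frame["replicate"] = (
            self.replicate if self.replicate is not None else np.zeros(len(self), int)
        )
        frame["defect_fraction"] = self.y
        if self.combination_index is not None:
            frame["combination"] = self.combination_index
        return frame

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "DefectDataset":
        missing = [c for c in CSV_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"missing required columns: {missing}")
        return cls(
            X=frame[list(FEATURE_NAMES)].to_numpy(dtype=float),
            y=frame["defect_fraction"].to_numpy(dtype=float),
            combination_index=(
                frame["combination"].to_numpy() if "combination" in frame.columns else None
            ),
            replicate=frame["replicate"].to_numpy(),
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "DefectDataset":
        return cls.from_frame(pd.read_csv(path))
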