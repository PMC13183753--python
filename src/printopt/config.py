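"""Printer profiles and run configuration.

A profile bundles the per-printer constants: KRR regularization strength
(0.5 batch / 0.7 continuous), the void gray-level threshold (0.45 batch /
0.35 continuous) and the forest hyperparameters.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import yaml

from .adaptive import SearchSpace
from .forest import BATCH_FOREST, CONTINUOUS_FOREST, ForestConfig
from .krr import KernelConfig
from .synthetic import FactorLevels, ResponseSurface

__all__ = ["PrinterProfile", "RunConfig", "BATCH_PROFILE", "CONTINUOUS_PROFILE",
           "get_profile"]


@dataclass(frozen=True)
class PrinterProfile:
    name: str
    krr_lambda: float
    void_threshold: float
    forest: ForestConfig
    kernel: KernelConfig = KernelConfig()


BATCH_PROFILE = PrinterProfile(
    name="batch", krr_lambda=0.5, void_threshold=0.45, forest=BATCH_FOREST,
)
CONTINUOUS_PROFILE = PrinterProfile(
    name="continuous", krr_lambda=0.7, void_threshold=0.35,
    forest=CONTINUOUS_FOREST,
)

_PROFILES = {"batch": BATCH_PROFILE, "continuous": CONTINUOUS_PROFILE}


def get_profile(name: str) -> PrinterProfile:
    try:
        return _PROFILES[name]
    except KeyError:
        raise ValueError(
            f"unknown profile '{name}'; expected one of {sorted(_PROFILES)}"
        ) from None


@dataclass
class RunConfig:
    """Everything an end-to-end desk-scale run needs."""

    profile: PrinterProfile = BATCH_PROFILE
    levels: FactorLevels = field(default_factory=FactorLevels)
    surface: ResponseSurface = field(default_factory=ResponseSurface)
    space: SearchSpace = field(default_factory=SearchSpace)
    replicates: int = 5
    test_share: float = 0.20
    targets: tuple[float, ...] = (0.0, 0.15)
    target_tolerances: tuple[float, ...] = (0.01, 0.03)
    budget: int = 25
    initial_design_size: int = 20
    seed: int = 0
    forest_trees: int | None = None   # override tree count for quick runs

    def effective_forest(self) -> ForestConfig:
        forest = self.profile.forest
        if self.forest_trees is not None:
            forest = replace(forest, n_trees=self.forest_trees)
        return forest

    # ------------------------------------------------------------------
    # YAML round trip
    # ------------------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "profile": self.profile.name,
            "levels": {k: list(v) for k, v in self.levels.as_dict().items()},
            "surface": asdict(self.surface),
            "space": {
                k: list(getattr(self.space, k))
                for k in ("print_speed", "infill_density",
                          "print_temperature", "flow_rate")
            },
            "replicates": self.replicates,
            "test_share": self.test_share,
            "targets": list(self.targets),
            "target_tolerances": list(self.target_tolerances),
            "budget": self.budget,
            "initial_design_size": self.initial_design_size,
            "seed": self.seed,
            "forest_trees": self.forest_trees,
        }

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_dict(cls, payload: dict) -> "RunConfig":
        cfg = cls()
        kwargs: dict = {}
        if "profile" in payload:
            kwargs["profile"] = get_profile(payload["profile"])
        if "levels" in payload:
            kwargs["levels"] = FactorLevels(
                **{k: tuple(v) for k, v in payload["levels"].items()}
            )
        if "surface" in payload:
            kwargs["surface"] = ResponseSurface(**payload["surface"])
        if "space" in payload:
            kwargs["space"] = SearchSpace(
                **{k: tuple(v) for k, v in payload["space"].items()}
            )
        for key in ("replicates", "test_share", "budget",
                    "initial_design_size", "seed", "forest_trees"):
            if key in payload:
                kwargs[key] = payload[key]
        for key in ("targets", "target_tolerances"):
            if key in payload:
                kwargs[key] = tuple(payload[key])
        return replace(cfg, **kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
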