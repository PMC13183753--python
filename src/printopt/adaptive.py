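"""Adaptive design: fit a GP surrogate, score a candidate grid with
Expected Improvement, run the suggested experiment, augment, repeat.

Nonzero defect targets are handled by minimizing the deviation objective
|defect - target|: the GP is fitted to replicate-level deviations, mu* is
the smallest deviation measured so far, and the loop stops once a
measured defect lands within the tolerance band around the target (or
the evaluation budget is exhausted).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import FEATURE_NAMES, DefectDataset
from .gp import (DEFAULT_NOISE_GRID, DEFAULT_THETA_GRID, GPModel,
                 candidate_probability, expected_improvement, gp_fit,
                 gp_predict)
from .preprocessing import ScalingState, apply_scaler, fit_scaler
from .synthetic import PrintParameters

__all__ = [
    "SearchSpace",
    "CandidateScore",
    "IterationRecord",
    "OptimizationTrace",
    "build_search_space",
    "score_candidates",
    "select_best",
    "suggest_next",
    "suggest_top_k",
    "run_adaptive_loop",
]


@dataclass(frozen=True)
class SearchSpace:
    """Inclusive (start, stop, step) grid ranges per factor.

    Defaults span the regions the study's suggestion tables draw from:
    speed 10-50, infill 5-40, temperature 180-220, flow 20-120, all in
    steps of 5.
    """

    print_speed: tuple[float, float, float] = (10.0, 50.0, 5.0)
    infill_density: tuple[float, float, float] = (5.0, 40.0, 5.0)
    print_temperature: tuple[float, float, float] = (180.0, 220.0, 5.0)
    flow_rate: tuple[float, float, float] = (20.0, 120.0, 5.0)

    def axis(self, name: str) -> np.ndarray:
        start, stop, step = getattr(self, name)
        if step <= 0:
            raise ValueError(f"step for '{name}' must be > 0")
        return np.arange(start, stop + 0.5 * step, step)


def _key(arr: np.ndarray) -> tuple[float, ...]:
    return tuple(np.round(np.asarray(arr, dtype=float), 9))


def build_search_space(
    space: SearchSpace | None = None,
    exclude: DefectDataset | list[PrintParameters] | None = None,
) -> list[PrintParameters]:
    """Full candidate grid in deterministic (lexicographic) order.

    Points already present in ``exclude`` (a dataset or parameter list)
    are dropped.
    """
    space = space or SearchSpace()
    axes = [space.axis(name) for name in FEATURE_NAMES]
    mesh = np.stack(
        [m.ravel() for m in np.meshgrid(*axes, indexing="ij")], axis=1
    )
    seen: set[tuple[float, ...]] = set()
    if exclude is not None:
        rows = exclude.X if isinstance(exclude, DefectDataset) else [
            p.as_array() for p in exclude
        ]
        seen = {_key(r) for r in rows}
    candidates = [
        PrintParameters.from_array(row) for row in mesh if _key(row) not in seen
    ]
    if not candidates:
        raise ValueError("search space is empty after exclusions")
    return candidates


@dataclass(frozen=True)
class CandidateScore:
    """Posterior moments and acquisition value for one candidate."""

    params: PrintParameters
    mean: float
    sd: float
    ei: float


def score_candidates(
    gp: GPModel,
    scaler: ScalingState,
    candidates: list[PrintParameters],
    mu_star: float,
) -> list[CandidateScore]:
    """Posterior mean/sd and Expected Improvement for every candidate."""
    if not candidates:
        raise ValueError("need at least one candidate")
    X = np.stack([c.as_array() for c in candidates])
    mu, sd = gp_predict(gp, apply_scaler(scaler, X))
    ei = expected_improvement(mu_star, mu, sd)
    return [
        CandidateScore(params=c, mean=float(m), sd=float(s), ei=float(e))
        for c, m, s, e in zip(candidates, mu, sd, ei)
    ]


def select_best(scores: list[CandidateScore]) -> int:
    """Index of the winning candidate.

    Ordering: highest EI first; among EI ties the lowest posterior mean
    (pure exploitation when all uncertainties vanish); then the lowest
    candidate index.
    """
    best = 0
    for i, s in enumerate(scores[1:], start=1):
        b = scores[best]
        if s.ei > b.ei + 1e-15 or (abs(s.ei - b.ei) <= 1e-15 and s.mean < b.mean - 1e-15):
            best = i
    return best


def suggest_next(
    gp: GPModel,
    scaler: ScalingState,
    candidates: list[PrintParameters],
    mu_star: float,
) -> tuple[PrintParameters, list[CandidateScore]]:
    """argmax-EI candidate plus the full score table for audit."""
    scores = score_candidates(gp, scaler, candidates, mu_star)
    return scores[select_best(scores)].params, scores


def suggest_top_k(
    scores: list[CandidateScore],
    k: int,
    space: SearchSpace | None = None,
    min_grid_distance: int = 1,
) -> list[CandidateScore]:
    """Top-k suggestions by EI, thinned to avoid near-duplicate grid points.

    Two suggestions must differ by at least ``min_grid_distance`` steps in
    some factor; this mirrors reporting several distinct candidate rows
    per target rather than a cluster around one grid cell.
    """
    space = space or SearchSpace()
    steps = np.array([getattr(space, n)[2] for n in FEATURE_NAMES])
    order = sorted(range(len(scores)),
                   key=lambda i: (-scores[i].ei, scores[i].mean, i))
    chosen: list[CandidateScore] = []
    for i in order:
        cand = scores[i].params.as_array()
        ok = all(
            np.max(np.abs(cand - c.params.as_array()) / steps)
            >= min_grid_distance - 1e-9
            for c in chosen
        )
        if ok:
            chosen.append(scores[i])
        if len(chosen) == k:
            break
    return chosen


def scores_to_frame(
    scores: list[CandidateScore],
    target: float | None = None,
    tolerance: float | None = None,
) -> pd.DataFrame:
    """Score table in the suggestion-table layout (mu, sigma, EI, probability)."""
    rows = []
    for s in scores:
        row = dict(zip(FEATURE_NAMES, s.params.as_array()))
        row.update({"mean": s.mean, "sd": s.sd, "ei": s.ei})
        if target is not None and tolerance is not None:
            row["probability"] = candidate_probability(
                s.mean, s.sd, target, tolerance
            )
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class IterationRecord:
    iteration: int
    params: PrintParameters
    predicted_mean: float      # posterior mean of the deviation objective
    predicted_sd: float
    ei: float
    measured_defect: float
    best_deviation: float      # cumulative min |defect - target|


@dataclass
class OptimizationTrace:
    target: float
    tolerance: float
    iterations: list[IterationRecord]
    stop_reason: str           # "target-met" | "budget-exhausted" | "space-exhausted"
    dataset: DefectDataset     # initial data plus every evaluated candidate

    @property
    def n_evaluations(self) -> int:
        return len(self.iterations)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rec in self.iterations:
            row = dict(zip(FEATURE_NAMES, rec.params.as_array()))
            row.update({
                "iteration": rec.iteration,
                "predicted_mean": rec.predicted_mean,
                "predicted_sd": rec.predicted_sd,
                "ei": rec.ei,
                "measured_defect": rec.measured_defect,
                "best_deviation": rec.best_deviation,
            })
            rows.append(row)
        return pd.DataFrame(rows)


def run_adaptive_loop(
    initial: DefectDataset,
    evaluator,
    target: float,
    tolerance: float = 0.01,
    budget: int = 25,
    seed: int | None = None,
    space: SearchSpace | None = None,
    theta_grid: tuple[float, ...] = DEFAULT_THETA_GRID,
    noise_grid: tuple[float, ...] = DEFAULT_NOISE_GRID,
) -> OptimizationTrace:
    """Closed-loop optimization toward a targeted defect level.

    Per iteration: standardize the accumulated features, fit the GP to
    the deviations |defect - target|, score the not-yet-evaluated grid
    candidates with EI against the best deviation so far, evaluate the
    argmax candidate with ``evaluator`` and append the measurement.
    Stops as soon as a measured defect lies within ``tolerance`` of the
    target, or after ``budget`` evaluations.

    ``seed`` is accepted for signature symmetry with the generators; the
    loop itself is deterministic given its inputs (any stochasticity
    lives in the evaluator).
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    if len(initial) == 0:
        raise ValueError("initial dataset must be non-empty")
    space = space or SearchSpace()
    data = initial
    records: list[IterationRecord] = []

    best_dev = float(np.min(np.abs(data.y - target)))
    if best_dev <= tolerance:
        return OptimizationTrace(target, tolerance, [], "target-met", data)

    stop_reason = "budget-exhausted"
    for it in range(1, budget + 1):
        scaler = fit_scaler(data.X, allow_constant=True)
        deviations = np.abs(data.y - target)
        gp = gp_fit(apply_scaler(scaler, data.X), deviations,
                    theta_grid, noise_grid)
        try:
            candidates = build_search_space(space, exclude=data)
        except ValueError:
            stop_reason = "space-exhausted"
            break
        mu_star = float(deviations.min())
        best, scores = suggest_next(gp, scaler, candidates, mu_star)
        chosen = scores[select_best(scores)]
        measured = float(evaluator(best))
        data = data.append_row(best.as_array(), measured)
        best_dev = min(best_dev, abs(measured - target))
        records.append(IterationRecord(
            iteration=it, params=best,
            predicted_mean=chosen.mean, predicted_sd=chosen.sd, ei=chosen.ei,
            measured_defect=measured, best_deviation=best_dev,
        ))
        if abs(measured - target) <= tolerance:
            stop_reason = "target-met"
            break

    return OptimizationTrace(target, tolerance, records, stop_reason, data)
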