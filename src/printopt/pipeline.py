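"""End-to-end desk-scale pipeline reproducing the study design.

Stages: full-factorial DoE on the virtual printer -> replicate
measurements -> 80:20 split -> standardization -> KRR training and
held-out metrics -> forest feature importance -> adaptive-design loop for
each configured defect target.  Every artifact (CSV, JSON, log, plot)
lands in the run directory together with a manifest capturing the config
and seeds, so a run is fully reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict
from pathlib import Path

import matplotlib
import numpy as np

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from . import __version__
from .adaptive import build_search_space, run_adaptive_loop
from .config import RunConfig
from .dataset import FEATURE_NAMES
from .forest import forest_importance
from .krr import compute_metrics, grid_search_cv, krr_fit, krr_predict
from .preprocessing import apply_scaler, fit_scaler, split_dataset
from .synthetic import (generate_full_factorial, make_surface_evaluator,
                        sample_measurements)

log = logging.getLogger("printopt")

__all__ = ["run_pipeline"]


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            log.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except Exception:
                log.exception("stage %s: FAILED", name)
                raise RuntimeError(f"pipeline stage '{name}' failed") from None
            log.info("stage %s: done", name)
            return out
        return inner
    return wrap


def run_pipeline(config: RunConfig, outdir: str | Path | None = None) -> Path:
    """Run every stage and return the run directory."""
    if outdir is None:
        outdir = Path("printopt-run-" + time.strftime("%Y%m%d-%H%M%S"))
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        _run(config, outdir)
    finally:
        log.removeHandler(handler)
        handler.close()
    return outdir


def _run(config: RunConfig, outdir: Path) -> None:
    config_dict = config.to_dict()
    config_hash = hashlib.sha256(
        json.dumps(config_dict, sort_keys=True).encode()
    ).hexdigest()

    # ---- design + virtual measurements --------------------------------
    design = _stage("doe")(generate_full_factorial)(config.levels)
    dataset = _stage("simulate")(sample_measurements)(
        config.surface, design, config.replicates, seed=config.seed
    )
    dataset.to_csv(outdir / "measurements.csv")

    # ---- split + scaling ----------------------------------------------
    train, test = _stage("split")(split_dataset)(
        dataset, config.test_share, seed=config.seed
    )
    scaler = fit_scaler(train.X)
    scaler.to_json(outdir / "scaler.json")

    # ---- KRR surrogate -------------------------------------------------
    @_stage("krr")
    def train_krr():
        lam_grid = tuple(sorted({0.01, 0.05, 0.1, 0.3, config.profile.krr_lambda, 1.0}))
        lam, kernel, cv_table = grid_search_cv(
            apply_scaler(scaler, train.X), train.y,
            lam_grid=lam_grid, kernel_grid=(config.profile.kernel,),
            seed=config.seed,
        )
        cv_table.to_csv(outdir / "krr_cv.csv", index=False)
        model = krr_fit(apply_scaler(scaler, train.X), train.y, lam, kernel)
        model.to_json(outdir / "krr_model.json")
        pred = krr_predict(model, apply_scaler(scaler, test.X))
        metrics = compute_metrics(test.y, pred)
        (outdir / "metrics.json").write_text(
            json.dumps({"lambda": lam, **metrics.as_dict()}, indent=2)
        )
        return metrics

    metrics = train_krr()

    # ---- feature importance -------------------------------------------
    @_stage("importance")
    def importance():
        vec, _ = forest_importance(
            dataset.X, dataset.y, config.effective_forest(), seed=config.seed
        )
        lines = ["feature,importance"] + [
            f"{name},{val:.6f}" for name, val in zip(FEATURE_NAMES, vec)
        ]
        (outdir / "importance.csv").write_text("\n".join(lines) + "\n")
        fig, ax = plt.subplots(figsize=(5, 3))
        order = np.argsort(vec)
        ax.barh([FEATURE_NAMES[i] for i in order], vec[order])
        ax.set_xlabel("MDI feature importance")
        fig.tight_layout()
        fig.savefig(outdir / "importance.png", dpi=120)
        plt.close(fig)
        return vec

    importance_vec = importance()

    # ---- adaptive loops ------------------------------------------------
    @_stage("adaptive")
    def adaptive():
        rng = np.random.default_rng(config.seed)
        grid = build_search_space(config.space)
        summaries = []
        for target, tol in zip(config.targets, config.target_tolerances):
            init_idx = rng.choice(len(grid), size=config.initial_design_size,
                                  replace=False)
            evaluator = make_surface_evaluator(
                config.surface, seed=int(rng.integers(2**31))
            )
            init_points = [grid[i] for i in init_idx]
            initial = sample_measurements(
                config.surface, init_points, replicates=1,
                seed=int(rng.integers(2**31)),
            )
            trace = run_adaptive_loop(
                initial, evaluator, target=target, tolerance=tol,
                budget=config.budget, space=config.space,
            )
            tag = f"{target:.2f}".replace(".", "p")
            trace.to_frame().to_csv(outdir / f"trace_target_{tag}.csv", index=False)
            summaries.append({
                "target": target, "tolerance": tol,
                "stop_reason": trace.stop_reason,
                "evaluations": trace.n_evaluations,
                "best_deviation": (trace.iterations[-1].best_deviation
                                   if trace.iterations else 0.0),
            })
            log.info("target %.2f: %s after %d evaluations",
                     target, trace.stop_reason, trace.n_evaluations)
        return summaries

    summaries = adaptive()

    manifest = {
        "version": __version__,
        "config": config_dict,
        "config_hash": config_hash,
        "profile": config.profile.name,
        "krr_lambda": config.profile.krr_lambda,
        "void_threshold": config.profile.void_threshold,
        "seed": config.seed,
        "metrics": metrics.as_dict(),
        "importance": dict(zip(FEATURE_NAMES, map(float, importance_vec))),
        "adaptive": summaries,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
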