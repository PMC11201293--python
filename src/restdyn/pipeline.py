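"""End-to-end orchestration: simulate -> features -> selection -> SVMs.

Two presets bundle the tunables:

* ``full`` — the full emulated study: 110 patients vs 106 controls, 90
  parcels, 240 volumes at TR=2 s, 6 HMM states, window 40 / overlap
  0.975, gamma x omega = {0.9,1,1.1} x {0.5,0.75,1}, 5 folds, 5,000
  permutations.  Hours-scale.
* ``desk`` — a reduced cohort (20/20 subjects, 20 parcels, 9^3 voxel
  grid, 200 permutations) with every stage identical in kind; minutes-
  scale on one CPU.

``run_all`` is deterministic given the config seed and caches its
feature table and metrics under the output directory so a rerun with
``resume=True`` skips completed stages.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify, hmm, multilayer, preprocess, static, synthetic
from .features import FeatureTable, assemble, config_hash, read_feature_table, write_feature_table

__all__ = ["RunConfig", "run_all", "report", "plot_roc"]

log = logging.getLogger("restdyn")


@dataclass
class RunConfig:
    """Everything an end-to-end run needs, with seeds."""

    sim: synthetic.SimulationConfig
    preset: str = "custom"
    mode: str = "voxel"  # 'voxel' or 'node'
    n_drop: int = 10
    low_hz: float = 0.01
    high_hz: float = 0.1
    window: int = 40
    overlap: float = 0.975
    gammas: tuple = multilayer.DEFAULT_GAMMAS
    omegas: tuple = multilayer.DEFAULT_OMEGAS
    ml_restarts: int = 3
    n_states: int = 6
    hmm_restarts: int = 3
    hmm_max_iter: int = 500
    r_threshold: float = 0.25
    strategies: tuple = ("spearman", "lasso", "t_lasso")
    kernels: tuple = classify.KERNELS
    n_folds: int = 5
    n_permutations: int = 200
    permutation_pairs: tuple = (("spearman", "rbf"), ("spearman", "sigmoid"))
    seed: int = 0

    @classmethod
    def desk(cls, seed: int = 0, **overrides) -> "RunConfig":
        sim = synthetic.SimulationConfig(
            n_patients=20,
            n_controls=20,
            n_parcels=20,
            n_volumes=240,
            voxel_grid=(9, 9, 9),
            seed=seed,
        )
        return cls(sim=sim, preset="desk", n_permutations=200, seed=seed, **overrides)

    @classmethod
    def full(cls, seed: int = 0, **overrides) -> "RunConfig":
        sim = synthetic.SimulationConfig(seed=seed)
        return cls(sim=sim, preset="full", n_permutations=5000, seed=seed, **overrides)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"] = self.sim.to_dict()
        return d


def _extract_features(cfg: RunConfig) -> FeatureTable:
    t0 = time.time()
    cohort = synthetic.generate_cohort(cfg.sim, make_volumes=cfg.mode == "voxel")
    log.info("simulated %d subjects in %.1fs", len(cohort.node_series), time.time() - t0)

    tr = cfg.sim.tr_seconds
    static_blocks: dict[str, pd.DataFrame] = {}
    nf_blocks: dict[str, pd.DataFrame] = {}
    filtered: dict[str, np.ndarray] = {}
    ss = np.random.SeedSequence(cfg.seed)
    nf_seeds = ss.spawn(len(cohort.node_series) + 1)
    hmm_seed = nf_seeds[-1]

    for i, sub in enumerate(cohort.subjects()):
        if cfg.mode == "voxel":
            if cohort.volumes is None or cohort.atlas is None:
                raise ValueError("voxel mode needs rendered volumes and an atlas")
            static_blocks[sub] = static.extract_static_voxel(
                cohort.volumes[sub],
                cohort.atlas,
                tr,
                n_drop=cfg.n_drop,
                low_hz=cfg.low_hz,
                high_hz=cfg.high_hz,
                r_threshold=cfg.r_threshold,
            )
        else:
            static_blocks[sub] = static.extract_static_node(
                cohort.node_series[sub],
                tr,
                n_drop=cfg.n_drop,
                low_hz=cfg.low_hz,
                high_hz=cfg.high_hz,
                r_threshold=cfg.r_threshold,
            )
        filt = preprocess.preprocess(
            cohort.node_series[sub], tr, n_drop=cfg.n_drop,
            low_hz=cfg.low_hz, high_hz=cfg.high_hz,
        )
        filtered[sub] = filt
        nf_blocks[sub] = multilayer.flexibility_grid(
            filt,
            gammas=cfg.gammas,
            omegas=cfg.omegas,
            window=cfg.window,
            overlap=cfg.overlap,
            seed=nf_seeds[i],
            n_restarts=cfg.ml_restarts,
        )
    log.info("static+multilayer features done at %.1fs", time.time() - t0)

    hmm_block, _, _ = hmm.extract_hmm_features(
        filtered,
        n_states=cfg.n_states,
        seed=int(hmm_seed.generate_state(1)[0] % (2**31 - 1)),
        n_restarts=cfg.hmm_restarts,
        max_iter=cfg.hmm_max_iter,
    )
    log.info("HMM features done at %.1fs", time.time() - t0)

    meta = {
        "config_hash": config_hash(cfg.to_dict()),
        "seed": cfg.seed,
        "preset": cfg.preset,
    }
    return assemble(
        cohort.manifest,
        static_blocks=static_blocks,
        nf_blocks=nf_blocks,
        hmm_block=hmm_block,
        meta=meta,
    )


def run_all(cfg: RunConfig, out_dir: str | Path | None = None, resume: bool = False) -> dict:
    """Run the full pipeline; returns (and optionally writes) the metrics.

    Output artifacts under ``out_dir``: ``features.tsv`` (+ JSON
    sidecar) and ``metrics.json``.  With ``resume=True`` an existing
    feature table (matching config hash) is reused instead of being
    recomputed.
    """
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()

    table: FeatureTable | None = None
    feat_path = out / "features.tsv" if out is not None else None
    if resume and feat_path is not None and feat_path.exists():
        cached = read_feature_table(feat_path)
        if cached.meta.get("config_hash") == config_hash(cfg.to_dict()):
            log.info("reusing cached feature table %s", feat_path)
            table = cached
    if table is None:
        table = _extract_features(cfg)
        if feat_path is not None:
            write_feature_table(table, feat_path)

    y = table.y
    metrics: dict = {
        "config": cfg.to_dict(),
        "config_hash": config_hash(cfg.to_dict()),
        "seed": cfg.seed,
        "n_features": table.n_features,
        "results": [],
        "permutations": {},
    }
    model_metrics: dict[str, classify.ModelMetrics] = {}
    for strategy in cfg.strategies:
        mm = classify.run_cv(
            table.features,
            y,
            strategy=strategy,
            kernels=cfg.kernels,
            n_folds=cfg.n_folds,
            seed=cfg.seed,
        )
        model_metrics[strategy] = mm
        metrics["results"].extend(mm.mean().to_dict(orient="records"))
        if mm.flags:
            metrics.setdefault("flags", []).extend(mm.flags)
    for strategy, kernel in cfg.permutation_pairs:
        key = f"{strategy}:{kernel}"
        metrics["permutations"][key] = classify.permutation_test(
            table.features,
            y,
            strategy=strategy,
            kernel=kernel,
            n_permutations=cfg.n_permutations,
            n_folds=cfg.n_folds,
            seed=cfg.seed,
        )
    metrics["wall_seconds"] = time.time() - t0
    if out is not None:
        (out / "metrics.json").write_text(json.dumps(metrics, indent=1, default=float))
    metrics["_model_metrics"] = model_metrics  # in-memory only (ROC points)
    return metrics


def report(metrics: dict) -> pd.DataFrame:
    """Human-readable summary: one row per strategy x kernel (fold means)."""
    rows = metrics.get("results", [])
    df = pd.DataFrame(rows, columns=["strategy", "kernel", "AUC", "accuracy", "sensitivity", "specificity"])
    if df.empty:
        log.warning("no classification results to report")
    return df


def plot_roc(mm: classify.ModelMetrics, path: str | Path) -> None:
    """Pooled-fold ROC curves per kernel, written as a figure file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for kernel in sorted({f.kernel for f in mm.folds}):
        fs = [f for f in mm.folds if f.kernel == kernel]
        scores = np.concatenate([f.scores for f in fs])
        y = np.concatenate([f.y_true for f in fs])
        fpr, tpr, _, auc = classify.roc_curve(y, scores)
        ax.plot(fpr, tpr, label=f"{kernel} (pooled AUC={auc:.3f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.5)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.set_title(f"ROC ({mm.strategy} selection)")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
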