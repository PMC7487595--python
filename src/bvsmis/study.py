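"""Replication-study driver: variable-selection performance across analysis strategies.

For each simulated dataset the driver runs up to three analyses and computes the
probability that a truly associated covariate ranks among the top k by posterior
inclusion probability:

* ``BVS_e_NMISS``   — error-aware sampler on all scheduled self-reports, using the
  generating sensitivity/specificity;
* ``BVS_e_NTFP``    — error-aware sampler after discarding reports that follow the
  first positive;
* ``BVS_perfect``   — sampler assuming perfect self-reports (phi1 = phi0 = 1); panels
  are always NTFP-truncated first, because a negative after a positive has zero
  probability under a perfect test.

Replicates receive independent seed substreams derived from the root seed with
``SeedSequence(root, spawn_key=(replicate, stream))``, so results are identical
regardless of worker count or completion order and any single replicate can be
reproduced in isolation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .likelihood import ModelData, TestAccuracy
from .sampler import ChainSummary, Hyperparameters, inclusion_probabilities, run_chain
from .simulate import SimulationDesign, apply_ntfp, generate_dataset

logger = logging.getLogger("bvsmis")

__all__ = [
    "STRATEGIES",
    "StudyConfig",
    "StudyResult",
    "top_k_true_probability",
    "false_positive_summary",
    "run_replication_study",
]

STRATEGIES = ("BVS_e_NMISS", "BVS_e_NTFP", "BVS_perfect")


@dataclass(frozen=True)
class StudyConfig:
    """Replication-study settings: design template, strategies, scale, seeding."""

    design: SimulationDesign
    replicates: int = 200
    strategies: tuple[str, ...] = STRATEGIES
    k: int = 5
    hyper: Hyperparameters = field(default_factory=Hyperparameters)
    seed: int = 0
    n_jobs: int = 1
    checkpoint_dir: str | None = None
    max_failure_fraction: float = 0.01

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("need at least one replicate")
        if self.k > self.design.P:
            raise ValueError("top-k cutoff cannot exceed the number of covariates")
        unknown = set(self.strategies) - set(STRATEGIES)
        if unknown:
            raise ValueError(f"unknown strategies: {sorted(unknown)}")


@dataclass
class StudyResult:
    """Per-strategy metric estimates with Monte-Carlo standard errors."""

    config: StudyConfig
    metric: dict[str, float]
    metric_se: dict[str, float]
    false_positives: dict[str, float]
    false_positives_se: dict[str, float]
    per_replicate: dict[str, np.ndarray]
    rankings: dict[str, np.ndarray]  # strategy -> (R, P) best-first rankings
    true_idx: list[np.ndarray]
    n_failed: int = 0

    def to_frame(self):
        import pandas as pd

        rows = []
        for s in self.config.strategies:
            rows.append(
                {
                    "strategy": s,
                    "cir": self.config.design.cir,
                    "sensitivity": self.config.design.accuracy.sensitivity,
                    "specificity": self.config.design.accuracy.specificity,
                    "metric": self.metric[s],
                    "se": self.metric_se[s],
                    "false_positives": self.false_positives[s],
                    "false_positives_se": self.false_positives_se[s],
                    "replicates": self.config.replicates,
                    "k": self.config.k,
                    "seed": self.config.seed,
                }
            )
        return pd.DataFrame(rows)


def top_k_true_probability(ranking: np.ndarray, true_idx: np.ndarray, k: int) -> float:
    """Fraction of truly associated covariates ranked among the top k (best-first)."""
    ranking = np.asarray(ranking)
    true_idx = np.asarray(true_idx)
    if k > ranking.size:
        raise ValueError("k exceeds the number of ranked covariates")
    if true_idx.size == 0:
        raise ValueError("need at least one true covariate")
    return float(np.isin(true_idx, ranking[:k]).mean())


def false_positive_summary(
    rankings: Sequence[np.ndarray], true_sets: Sequence[np.ndarray], k: int
) -> tuple[float, float]:
    """Mean (and SE) number of null covariates among the top k, over replicates."""
    counts = np.array(
        [np.sum(~np.isin(np.asarray(r)[:k], t)) for r, t in zip(rankings, true_sets)],
        dtype=float,
    )
    se = counts.std(ddof=1) / np.sqrt(counts.size) if counts.size > 1 else 0.0
    return float(counts.mean()), float(se)


def _strategy_inputs(dataset, strategy: str) -> tuple[list, TestAccuracy]:
    acc = dataset.design.accuracy
    if strategy == "BVS_e_NMISS":
        return dataset.panels, acc
    if strategy == "BVS_e_NTFP":
        return [apply_ntfp(p) for p in dataset.panels], acc
    if strategy == "BVS_perfect":
        return [apply_ntfp(p) for p in dataset.panels], TestAccuracy(1.0, 1.0)
    raise ValueError(f"unknown strategy {strategy!r}")


def run_replicate(config: StudyConfig, r: int) -> dict:
    """One replicate: simulate, analyze under every strategy, score the rankings."""
    data_rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(r, 0)))
    dataset = generate_dataset(config.design, data_rng)
    out: dict = {"replicate": r, "true_idx": dataset.true_idx.tolist()}
    for s_i, strategy in enumerate(config.strategies):
        panels, acc = _strategy_inputs(dataset, strategy)
        data = ModelData.from_panels(panels, dataset.Z, acc)
        chain_rng = np.random.default_rng(
            np.random.SeedSequence(config.seed, spawn_key=(r, 1 + s_i))
        )
        summary = run_chain(data, config.hyper, chain_rng)
        probs, ranking = inclusion_probabilities(summary)
        out[strategy] = {
            "metric": top_k_true_probability(ranking, dataset.true_idx, config.k),
            "ranking": ranking.tolist(),
            "probs": probs.tolist(),
        }
    return out


def _replicate_with_checkpoint(config: StudyConfig, r: int) -> dict | None:
    ckpt = None
    if config.checkpoint_dir is not None:
        ckpt = Path(config.checkpoint_dir) / f"replicate_{r:05d}.json"
        if ckpt.exists():
            return json.loads(ckpt.read_text())
    try:
        result = run_replicate(config, r)
    except Exception as exc:  # noqa: BLE001 - replicate-level containment
        logger.error("replicate %d failed: %s", r, exc)
        return None
    if ckpt is not None:
        ckpt.parent.mkdir(parents=True, exist_ok=True)
        ckpt.write_text(json.dumps(result))
    return result


def run_replication_study(config: StudyConfig) -> StudyResult:
    """Run all replicates and aggregate the top-k metric per strategy (mean +/- SE)."""
    if config.n_jobs > 1:
        from joblib import Parallel, delayed

        raw = Parallel(n_jobs=config.n_jobs)(
            delayed(_replicate_with_checkpoint)(config, r) for r in range(config.replicates)
        )
    else:
        raw = [_replicate_with_checkpoint(config, r) for r in range(config.replicates)]
    results = [r for r in raw if r is not None]
    n_failed = config.replicates - len(results)
    if n_failed > config.max_failure_fraction * config.replicates:
        raise RuntimeError(
            f"{n_failed}/{config.replicates} replicates failed (> "
            f"{config.max_failure_fraction:.0%} allowed): aborting the study"
        )
    metric: dict[str, float] = {}
    metric_se: dict[str, float] = {}
    fps: dict[str, float] = {}
    fps_se: dict[str, float] = {}
    per_rep: dict[str, np.ndarray] = {}
    rankings: dict[str, np.ndarray] = {}
    true_sets = [np.asarray(res["true_idx"]) for res in results]
    for s in config.strategies:
        vals = np.array([res[s]["metric"] for res in results])
        per_rep[s] = vals
        metric[s] = float(vals.mean())
        metric_se[s] = float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else 0.0
        ranks = np.array([res[s]["ranking"] for res in results])
        rankings[s] = ranks
        fps[s], fps_se[s] = false_positive_summary(list(ranks), true_sets, config.k)
    return StudyResult(
        config=config,
        metric=metric,
        metric_se=metric_se,
        false_positives=fps,
        false_positives_se=fps_se,
        per_replicate=per_rep,
        rankings=rankings,
        true_idx=true_sets,
        n_failed=n_failed,
    )
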