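"""End-to-end benchmark orchestration with bootstrap replication.

Replicate seeds derive deterministically from the master seed via
``numpy.random.SeedSequence([master_seed, replicate_index])``, so any
single replicate can be reproduced in isolation and identical master
seeds yield byte-identical JSON reports.
"""

from __future__ import annotations

import logging
import time
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
import yaml

from . import evaluation
from .cohort import (analysis_covariance, bootstrap_resample, default_parameters,
                     simulate_cross_sectional, simulate_longitudinal, SemParameters)
from .fci import fci_search
from .ges import fges_search
from .gold import build_gold_standard, time_suffix_map
from .graphs import MixedGraph, graph_to_text
from .knowledge import build_background_knowledge
from .sem import recovery_experiment, stepwise_search, summarize_recovery
from .stats import ScoreConfig

log = logging.getLogger(__name__)

__all__ = ["ExperimentConfig", "run_discovery_experiment", "run_recovery_study",
           "run_algorithm"]

ALGORITHMS = ("fges", "fci", "sem")


@dataclass
class ExperimentConfig:
    design: str = "cross_sectional"
    algorithms: tuple[str, ...] = ALGORITHMS
    knowledge_level: int = 2
    n: int | None = None                 # default: 1008 / 266 by design
    n_bootstraps: int = 100
    seed: int = 0
    alpha: float = 0.05
    penalty_discount: float = 1.0
    subsample_fraction: float = 1.0
    max_sem_iter: int | None = None      # discovery arm: run to no-improvement

    def __post_init__(self) -> None:
        if self.design not in ("cross_sectional", "longitudinal"):
            raise ValueError(f"unknown design {self.design!r}")
        unknown = set(self.algorithms) - set(ALGORITHMS)
        if unknown:
            raise ValueError(f"unknown algorithms {sorted(unknown)}")
        if self.n_bootstraps < 1:
            raise ValueError("n_bootstraps must be >= 1")
        if not 0 < self.subsample_fraction <= 1:
            raise ValueError("subsample_fraction must lie in (0, 1]")

    @property
    def default_n(self) -> int:
        return 1008 if self.design == "cross_sectional" else 266

    @classmethod
    def from_yaml(cls, text: str) -> "ExperimentConfig":
        doc = yaml.safe_load(text) or {}
        if "algorithms" in doc:
            doc["algorithms"] = tuple(doc["algorithms"])
        return cls(**doc)


def replicate_seed(master_seed: int, index: int) -> np.random.SeedSequence:
    return np.random.SeedSequence([master_seed, index])


def _seed_int(master_seed: int, index: int) -> int:
    return int(replicate_seed(master_seed, index).generate_state(1)[0])


def run_algorithm(algorithm: str, cov, knowledge, config: ExperimentConfig,
                  nodes: list[str]) -> MixedGraph:
    score_cfg = ScoreConfig(config.penalty_discount)
    if algorithm == "fges":
        return fges_search(cov, knowledge, score_cfg)
    if algorithm == "fci":
        return fci_search(cov, alpha=config.alpha, knowledge=knowledge)
    if algorithm == "sem":
        empty = MixedGraph(nodes, kind_hint="DAG")
        model, _, _ = stepwise_search(empty, cov, knowledge, score_cfg,
                                      max_iter=config.max_sem_iter)
        return model
    raise ValueError(f"unknown algorithm {algorithm!r}")


def _simulate(config: ExperimentConfig, params: SemParameters) -> pd.DataFrame:
    n = config.n or config.default_n
    sim = (simulate_cross_sectional if config.design == "cross_sectional"
           else simulate_longitudinal)
    return sim(params, n, seed=_seed_int(config.seed, 0))


def run_discovery_experiment(config: ExperimentConfig,
                             cohort: pd.DataFrame | None = None,
                             params: SemParameters | None = None) -> dict:
    """Bootstrap the cohort, run each algorithm per replicate, and report
    averaged metrics, occurrence rates and the consensus graph."""
    params = params or default_parameters()
    if cohort is None:
        cohort = _simulate(config, params)
    if config.subsample_fraction < 1.0:
        m = max(2, int(round(config.subsample_fraction * len(cohort))))
        rng = np.random.default_rng(replicate_seed(config.seed, 1))
        cohort = cohort.iloc[rng.choice(len(cohort), size=m, replace=False)]
        cohort = cohort.reset_index(drop=True)

    gold = build_gold_standard(config.design)
    nodes = list(analysis_covariance(cohort).names)
    knowledge = build_background_knowledge(
        config.knowledge_level, nodes,
        time_suffix_map(config.design) or None
        if config.knowledge_level == 3 else None)

    graphs: dict[str, list[MixedGraph]] = {a: [] for a in config.algorithms}
    failures: dict[str, int] = {a: 0 for a in config.algorithms}
    for b in range(config.n_bootstraps):
        resampled = bootstrap_resample(cohort, seed=_seed_int(config.seed, 100 + b))
        cov = analysis_covariance(resampled)
        for algo in config.algorithms:
            t0 = time.perf_counter()
            try:
                graphs[algo].append(run_algorithm(algo, cov, knowledge,
                                                  config, nodes))
            except Exception as exc:  # logged, not fatal
                failures[algo] += 1
                log.warning("replicate %d: %s failed: %s", b, algo, exc)
            log.info("replicate %d %s: %.2fs", b, algo,
                     time.perf_counter() - t0)

    report: dict = {"config": asdict(config), "algorithms": {}}
    for algo in config.algorithms:
        gs = graphs[algo]
        if not gs:
            report["algorithms"][algo] = {"failures": failures[algo]}
            continue
        per_run = [evaluation.score_graph(g, gold) for g in gs]
        rates = evaluation.occurrence_rates(gs)
        consensus = evaluation.consensus_graph(gs)
        cons_report = evaluation.score_graph(consensus, gold)
        precisions = [r.precision for r in per_run if r.precision is not None]
        report["algorithms"][algo] = {
            "failures": failures[algo],
            "bootstraps": len(gs),
            "mean_precision": float(np.mean(precisions)) if precisions else None,
            "mean_recall": float(np.mean([r.recall for r in per_run])),
            "mean_correct": float(np.mean([r.correct for r in per_run])),
            "mean_semi_correct": float(np.mean([r.semi_correct for r in per_run])),
            "mean_incorrect": float(np.mean([r.incorrect for r in per_run])),
            "occurrence_rates": {
                "--".join(sorted(pair)): rate
                for pair, rate in sorted(rates.items(),
                                         key=lambda kv: sorted(kv[0]))},
            "consensus_graph": graph_to_text(consensus),
            "consensus_precision": cons_report.precision,
            "consensus_recall": cons_report.recall,
        }
    return report


def run_recovery_study(config: ExperimentConfig,
                       cohort: pd.DataFrame | None = None,
                       params: SemParameters | None = None,
                       max_add: int = 5,
                       use_population_covariance: bool = False) -> dict:
    """Single- and pair-deletion recovery summary (one row per k)."""
    params = params or default_parameters()
    gold = build_gold_standard(config.design)
    if use_population_covariance:
        from .cohort import population_covariance
        cov = population_covariance(params, config.design,
                                    config.n or config.default_n)
    else:
        if cohort is None:
            cohort = _simulate(config, params)
        cov = analysis_covariance(cohort)
    nodes = list(cov.names)
    knowledge = build_background_knowledge(
        config.knowledge_level, nodes,
        time_suffix_map(config.design) or None
        if config.knowledge_level == 3 else None)
    score_cfg = ScoreConfig(config.penalty_discount)
    rows = []
    for k in (1, 2):
        results = recovery_experiment(gold, cov, k, max_add=max_add,
                                      knowledge=knowledge, config=score_cfg)
        rows.append({"edges_removed": k, **summarize_recovery(results)})
    return {"config": asdict(config), "rows": rows}
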