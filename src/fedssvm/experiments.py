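"""Experiment orchestration: accuracy-vs-rounds / accuracy-vs-volume /
utility-vs-cost curves on synthetic cohorts.

A run generates a cohort, carves off a test set, partitions the training
rows across m agents, then executes each requested method (cpds, fedavg,
local, oracle), recording test accuracy (percent), communication volume and
cost at the configured round checkpoints. Everything is a pure function of
the config seed.

Cost conventions (the axes of utility curves are not standardised anywhere,
so these are fixed, documented scalings):
  transmission cost = cumulative messages * 1e-3
  compute cost      = cumulative local gradient/prox evaluations * 1e-4
                      (2 evaluations per agent per cpds round; 2 per local
                      pass for fedavg/local)
Utility is linear: accuracy_percent - kappa * cost.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import cpds as _cpds
from .baselines import (LearningRateSchedule, fedavg_svm, prox_subgradient,
                        solve_centralized_qp)
from .datasets import (CohortSpec, Dataset, generate_dataset, partition,
                       train_test_split)
from .network import build_topology, metropolis_weights
from .scheduler import volume_gigabytes, CommLog
from .svm import Classifier, Hyperparams, predict_accuracy

__all__ = ["ExperimentConfig", "run_experiment", "utility", "write_metrics",
           "read_metrics", "METRIC_COLUMNS"]

METRIC_COLUMNS = ["method", "round", "gigabytes", "accuracy_percent",
                  "cost", "utility"]

_ALL_METHODS = ("cpds", "fedavg", "local", "oracle")


@dataclass
class ExperimentConfig:
    cohort: CohortSpec = field(default_factory=lambda: CohortSpec(
        n_samples=1000, n_continuous=10, n_binary=10, sparsity=5,
        signal_scale=1.0, label_noise=0.05, positive_fraction_target=0.4))
    m: int = 5
    topology: str = "star"
    topology_p: float = 0.5
    partition_mode: str = "label_skew"
    skew_alpha: float = 0.5
    test_fraction: float = 0.25
    hyperparams: Hyperparams = field(default_factory=lambda: Hyperparams(0.5, 0.2))
    max_rounds: int = 1000
    local_epochs: int = 5
    eta0: float = 0.1
    methods: tuple = ("cpds", "fedavg", "oracle")
    utility_kappa: float = 1.0
    cost_kind: str = "transmission"
    checkpoints: tuple = tuple(range(50, 1001, 50))
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.methods:
            raise ValueError("at least one method is required")
        unknown = set(self.methods) - set(_ALL_METHODS)
        if unknown:
            raise ValueError(f"unknown methods {sorted(unknown)}")
        cps = list(self.checkpoints)
        if cps != sorted(set(cps)) or (cps and cps[0] < 1):
            raise ValueError("checkpoints must be strictly increasing, >= 1")
        if self.cost_kind not in ("transmission", "compute"):
            raise ValueError("cost_kind must be 'transmission' or 'compute'")

    @classmethod
    def from_dict(cls, raw: dict) -> "ExperimentConfig":
        raw = dict(raw)
        if "cohort" in raw:
            raw["cohort"] = CohortSpec(**raw["cohort"])
        if "hyperparams" in raw:
            raw["hyperparams"] = Hyperparams(**raw["hyperparams"])
        for key in ("methods", "checkpoints"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    @classmethod
    def from_file(cls, path) -> "ExperimentConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["methods"] = list(self.methods)
        out["checkpoints"] = list(self.checkpoints)
        return out


def utility(accuracy_percent: float, cost: float, kappa: float) -> float:
    """Linear utility accuracy_percent - kappa * cost."""
    if not (0.0 <= accuracy_percent <= 100.0):
        raise ValueError("accuracy must lie in [0, 100]")
    if cost < 0 or kappa < 0:
        raise ValueError("cost and kappa must be nonnegative")
    return accuracy_percent - kappa * cost


def _costs(cfg: ExperimentConfig, messages: int, evals: int) -> float:
    if cfg.cost_kind == "transmission":
        return messages * 1e-3
    return evals * 1e-4


def _row(cfg, method, rnd, comm_bytes, messages, evals, acc):
    cost = _costs(cfg, messages, evals)
    acc_pct = 100.0 * acc
    return {"method": method, "round": int(rnd),
            "gigabytes": comm_bytes / 2**30, "accuracy_percent": acc_pct,
            "cost": cost, "utility": utility(acc_pct, cost, cfg.utility_kappa)}


def run_experiment(config: ExperimentConfig) -> pd.DataFrame:
    """Run every configured method and tabulate the checkpointed metrics.

    Stage failures are re-raised with the stage name attached. The result
    has one row per (method, checkpoint), columns ``METRIC_COLUMNS``.
    """
    stage = "generate"
    try:
        spec = dataclasses.replace(config.cohort, seed=config.seed)
        data = generate_dataset(spec)
        stage = "split"
        train, test = train_test_split(data, config.test_fraction,
                                       seed=config.seed + 1)
        stage = "partition"
        parts = partition(train, config.m, config.partition_mode,
                          config.skew_alpha, seed=config.seed + 2)
        stage = "graph"
        graph = metropolis_weights(build_topology(
            config.topology, config.m, config.topology_p,
            seed=config.seed + 3))

        rows: list[dict] = []
        checkpoints = list(config.checkpoints) or [config.max_rounds]
        hp = config.hyperparams

        for method in config.methods:
            stage = method
            if method == "oracle":
                sol = solve_centralized_qp(train, hp)
                _, acc = predict_accuracy(sol.classifier, test)
                for _ in checkpoints:
                    rows.append(_row(config, "oracle", 0, 0, 0, 0, acc))
            elif method == "cpds":
                rows.extend(_run_cpds(config, parts, graph, hp, test,
                                      checkpoints))
            elif method == "fedavg":
                rows.extend(_run_fedavg(config, parts, hp, test, checkpoints))
            elif method == "local":
                rows.extend(_run_local(config, parts, hp, test, checkpoints))
        return pd.DataFrame(rows, columns=METRIC_COLUMNS)
    except Exception as exc:
        raise RuntimeError(f"experiment failed in stage '{stage}': {exc}") from exc


def _run_cpds(cfg, parts, graph, hp, test, checkpoints):
    problems = _cpds.agent_problems(parts, hp)
    solver_cfg = _cpds.default_config(problems, graph,
                                      max_rounds=max(checkpoints),
                                      record_every=max(checkpoints))
    state = _cpds.initialize(problems, graph, solver_cfg)
    rows, targets = [], set(checkpoints)
    for rnd in range(1, max(checkpoints) + 1):
        _cpds.step(state)
        if rnd in targets:
            _, acc = predict_accuracy(state.averaged_classifier(), test)
            evals = 2 * graph.m * rnd
            rows.append(_row(cfg, "cpds", rnd, state.comm.bytes,
                             state.comm.messages, evals, acc))
    return rows


def _run_fedavg(cfg, parts, hp, test, checkpoints):
    schedule = LearningRateSchedule(eta0=cfg.eta0)
    rows = []
    clf, trace, comm = fedavg_svm(
        parts, hp, rounds=max(checkpoints), local_epochs=cfg.local_epochs,
        schedule=schedule, seed=cfg.seed, test_data=test,
        record_every=1)
    by_round = {t[0]: t for t in trace}
    for rnd in checkpoints:
        t = by_round[rnd]
        evals = 2 * cfg.m * cfg.local_epochs * rnd
        rows.append(_row(cfg, "fedavg", rnd, t[4], t[3], evals, t[5]))
    return rows


def _run_local(cfg, parts, hp, test, checkpoints):
    """No-communication baseline: each agent trains alone; the reported
    accuracy is the mean test accuracy of the per-agent models."""
    n = parts.n_total
    rows = []
    xs = [np.zeros(p.n_features + 1) for p in parts.parts]
    done = 0
    for rnd in checkpoints:
        iters = (rnd - done) * cfg.local_epochs
        for j, part in enumerate(parts.parts):
            hp_local = Hyperparams(hp.psi * part.n_samples / n,
                                   hp.rho * part.n_samples / n)
            xs[j] = prox_subgradient(part, hp_local, iters=iters, x0=xs[j],
                                     eta0=cfg.eta0,
                                     t_offset=done * cfg.local_epochs)
        done = rnd
        accs = [predict_accuracy(Classifier(x[:-1], x[-1]), test)[1]
                for x in xs]
        evals = 2 * cfg.m * cfg.local_epochs * rnd
        rows.append(_row(cfg, "local", rnd, 0, 0, evals, float(np.mean(accs))))
    return rows


def write_metrics(table: pd.DataFrame, path) -> None:
    """CSV with the fixed METRIC_COLUMNS order; write-read-write idempotent."""
    missing = [c for c in METRIC_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"metrics table missing columns {missing}")
    table[METRIC_COLUMNS].to_csv(path, index=False)


def read_metrics(path) -> pd.DataFrame:
    # round_trip parsing: the written shortest-repr floats must come back
    # bit-identical for write/read/write idempotence
    return pd.read_csv(path, float_precision="round_trip")
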