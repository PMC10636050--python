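"""Experiment harnesses: leave-one-center-out federation and n-fold federated CV.

Exp1: each center in turn acts as the evaluating server while the remaining
centers train a federated model under each aggregation strategy; local-only
("NoFed") baselines train the identical architecture on a single center for
the same total epoch budget.

Exp2: a pooled cohort is split into n folds (random or stratified); one fold
is held out for evaluation, the remaining n-1 folds become n-1 clients, and
the rotation yields mean +/- std curves for both the federated and the
centralized arm on identical splits.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .aggregation import StrategyConfig
from .encoding import CohortDataset, concat_cohorts
from .federated import ClientNode, FLRunConfig, run_federated_training
from .metrics import MetricsReport, evaluate, hanley_mcneil_test
from .model import ModelConfig, init_model, predict, train_local

__all__ = ["Exp1Config", "Exp2Config", "Exp1Result", "run_exp1", "run_exp2"]


def _model_config_for(dataset: CohortDataset, template: ModelConfig | None) -> ModelConfig:
    if template is None:
        template = ModelConfig(n_genes=dataset.n_genes, n_features=dataset.tensor.shape[1])
    return replace(
        template, n_genes=dataset.n_genes, n_features=dataset.tensor.shape[1]
    )


@dataclass(frozen=True)
class Exp1Config:
    strategies: tuple[StrategyConfig, ...] = tuple(
        StrategyConfig(name=n) for n in ("fedavg", "fedavgm", "fedadam", "fedyogi", "fedadagrad")
    )
    n_rounds: int = 5
    local_epochs: int = 100
    model: ModelConfig | None = None
    seed: int = 0


@dataclass
class Exp1Result:
    table: pd.DataFrame  # one row per (held-out center, method)
    hm_tests: pd.DataFrame  # best-FL vs each NoFed AUC comparison
    reports: dict[tuple[str, str], MetricsReport] = field(default_factory=dict)


def _train_nofed(
    train_set: CohortDataset, config: ModelConfig, total_epochs: int, seed: int
):
    cfg = replace(config, epochs=total_epochs, seed=seed)
    params, _ = train_local(init_model(cfg), train_set, cfg)
    return params


def run_exp1(
    centers: Sequence[CohortDataset], config: Exp1Config = Exp1Config()
) -> Exp1Result:
    """Rotate the evaluating server over the centers; compare FL vs local-only."""
    if len(centers) < 3:
        raise ValueError("need at least 3 centers (>=2 training per rotation)")
    rows: list[dict] = []
    hm_rows: list[dict] = []
    reports: dict[tuple[str, str], MetricsReport] = {}

    for held_idx, eval_set in enumerate(centers):
        train_centers = [c for i, c in enumerate(centers) if i != held_idx]
        model_cfg = _model_config_for(eval_set, config.model)

        fl_scores: dict[str, np.ndarray] = {}
        for strategy in config.strategies:
            clients = [
                ClientNode(id=c.center_id, _dataset=c, config=model_cfg)
                for c in train_centers
            ]
            run_cfg = FLRunConfig(
                n_rounds=config.n_rounds,
                local_epochs=config.local_epochs,
                strategy=strategy,
                seed=config.seed,
            )
            params, _ = run_federated_training(clients, run_cfg)
            scores = predict(params, eval_set)
            fl_scores[strategy.name] = scores
            report = evaluate(eval_set.labels, scores)
            reports[(eval_set.center_id, strategy.name)] = report
            rows.append(
                {"held_out": eval_set.center_id, "method": strategy.name}
                | report.as_row()
            )

        nofed_scores: dict[str, np.ndarray] = {}
        for c in train_centers:
            params = _train_nofed(
                c,
                model_cfg,
                total_epochs=config.n_rounds * config.local_epochs,
                seed=config.seed,
            )
            scores = predict(params, eval_set)
            method = f"nofed({c.center_id})"
            nofed_scores[method] = scores
            report = evaluate(eval_set.labels, scores)
            reports[(eval_set.center_id, method)] = report
            rows.append(
                {"held_out": eval_set.center_id, "method": method} | report.as_row()
            )

        best_name = max(
            fl_scores, key=lambda k: reports[(eval_set.center_id, k)].auc
        )
        for method, scores in nofed_scores.items():
            res = hanley_mcneil_test(eval_set.labels, fl_scores[best_name], scores)
            hm_rows.append(
                {
                    "held_out": eval_set.center_id,
                    "best_fl": best_name,
                    "vs": method,
                    "auc_fl": res.auc_a,
                    "auc_nofed": res.auc_b,
                    "z": res.z,
                    "p": res.p,
                }
            )

    return Exp1Result(
        table=pd.DataFrame(rows), hm_tests=pd.DataFrame(hm_rows), reports=reports
    )


@dataclass(frozen=True)
class Exp2Config:
    fold_counts: tuple[int, ...] = (3, 5, 7, 9, 11, 13, 15, 17, 21, 31)
    split_modes: tuple[str, ...] = ("random", "stratified")
    n_rounds: int = 5
    local_epochs: int = 100
    model: ModelConfig | None = None
    seed: int = 0
    max_rotations: int | None = None  # cap rotations per (n, mode) for speed

    def __post_init__(self) -> None:
        if any(n < 2 for n in self.fold_counts):
            raise ValueError("fold counts must be >= 2")
        for m in self.split_modes:
            if m not in ("random", "stratified"):
                raise ValueError(f"unknown split mode {m!r}")


def run_exp2(pooled: CohortDataset, config: Exp2Config = Exp2Config()) -> pd.DataFrame:
    """n-fold federated cross-validation vs centralized training on the same splits.

    Returns one row per (n_folds, split_mode, arm) with mean and std of AUC
    and AUPRC over the rotations.
    """
    from .synthetic import split_random, split_stratified

    rows: list[dict] = []
    for mode in config.split_modes:
        splitter = split_random if mode == "random" else split_stratified
        for n_folds in config.fold_counts:
            folds = splitter(pooled, n_folds, config.seed)
            n_rot = len(folds) if config.max_rotations is None else min(
                len(folds), config.max_rotations
            )
            fl_reports: list[MetricsReport] = []
            central_reports: list[MetricsReport] = []
            for held in range(n_rot):
                eval_fold = folds[held]
                train_folds = [f for j, f in enumerate(folds) if j != held]
                train_ids = {s for f in train_folds for s in f.sample_ids}
                if not train_ids.isdisjoint(eval_fold.sample_ids):
                    raise RuntimeError("evaluation fold overlaps client training data")
                if np.unique(eval_fold.labels).size < 2:
                    continue  # AUC undefined on a one-class fold
                model_cfg = _model_config_for(pooled, config.model)

                clients = [
                    ClientNode(id=f.center_id, _dataset=f, config=model_cfg)
                    for f in train_folds
                ]
                run_cfg = FLRunConfig(
                    n_rounds=config.n_rounds,
                    local_epochs=config.local_epochs,
                    strategy=StrategyConfig(name="fedavg"),
                    seed=config.seed + held,
                )
                params, _ = run_federated_training(clients, run_cfg)
                fl_reports.append(
                    evaluate(eval_fold.labels, predict(params, eval_fold))
                )

                merged = concat_cohorts(train_folds, center_id="central")
                params_c = _train_nofed(
                    merged,
                    model_cfg,
                    total_epochs=config.n_rounds * config.local_epochs,
                    seed=config.seed + held,
                )
                central_reports.append(
                    evaluate(eval_fold.labels, predict(params_c, eval_fold))
                )

            for arm, reports in (("fl", fl_reports), ("central", central_reports)):
                if not reports:
                    continue
                aucs = np.array([r.auc for r in reports])
                auprcs = np.array([r.auprc for r in reports])
                rows.append(
                    {
                        "n_folds": n_folds,
                        "split_mode": mode,
                        "arm": arm,
                        "n_rotations": len(reports),
                        "auc_mean": float(aucs.mean()),
                        "auc_std": float(aucs.std()),
                        "auprc_mean": float(auprcs.mean()),
                        "auprc_std": float(auprcs.std()),
                    }
                )
    return pd.DataFrame(rows)
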