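"""In-process simulation of the centralized synchronous round protocol.

One round: the server broadcasts the global parameter vector; every client
trains locally for E epochs from the received parameters with a fresh local
optimizer state; the server collects (parameters, sample count) pairs and
applies the configured aggregation strategy.  Clients expose only
``train(params) -> ClientUpdate``; the server never touches client data.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .aggregation import AggregationState, ClientUpdate, StrategyConfig, aggregate
from .encoding import CohortDataset
from .model import ModelConfig, ModelParameters, init_model, predict, train_local

__all__ = [
    "ClientNode",
    "FLRunConfig",
    "RoundLog",
    "derive_client_rng",
    "run_round",
    "run_federated_training",
]


@dataclass
class ClientNode:
    """A data-holding participant.  Only parameter vectors leave this object."""

    id: str
    _dataset: CohortDataset
    config: ModelConfig
    rng: np.random.Generator | None = None

    def __post_init__(self) -> None:
        if self._dataset.n_samples == 0:
            raise ValueError(f"client {self.id!r}: dataset must be non-empty")
        if self.rng is None:
            self.rng = np.random.default_rng(self.config.seed)

    @property
    def n_samples(self) -> int:
        return self._dataset.n_samples

    def train(self, params: np.ndarray) -> ClientUpdate:
        """Local training from the broadcast parameters; fresh optimizer state."""
        start = ModelParameters.from_vector(
            np.asarray(params, dtype=float),
            self.config.n_genes,
            self.config.g_hidden_width,
            self.config.n_features,
        )
        trained, _ = train_local(start, self._dataset, self.config, rng=self.rng)
        return ClientUpdate(trained.to_vector(), self.n_samples)


@dataclass(frozen=True)
class FLRunConfig:
    """Round budget, local epoch budget, strategy and master seed."""

    n_rounds: int = 5
    local_epochs: int = 100
    strategy: StrategyConfig = field(default_factory=StrategyConfig)
    seed: int = 0
    early_stop: bool = False  # optional stop on non-improving held-out loss

    def __post_init__(self) -> None:
        if self.n_rounds < 1 or self.local_epochs < 1:
            raise ValueError("n_rounds and local_epochs must be >= 1")


@dataclass
class RoundLog:
    round_index: int
    client_sizes: dict[str, int]
    client_weights: dict[str, float]
    global_checksum: float
    eval_metrics: dict[str, float] = field(default_factory=dict)


def derive_client_rng(master_seed: int, client_id: str) -> np.random.Generator:
    """Deterministic per-client generator keyed on the master seed and client id.

    Keying on the id (not the list position) makes runs invariant to the
    order in which clients are enumerated.
    """
    return np.random.default_rng(
        np.random.SeedSequence([master_seed, zlib.crc32(client_id.encode())])
    )


def run_round(
    global_params: np.ndarray,
    clients: Sequence[ClientNode],
    strategy: StrategyConfig,
    state: AggregationState,
) -> tuple[np.ndarray, AggregationState, RoundLog]:
    """One broadcast / local-train / collect / aggregate cycle."""
    global_params = np.asarray(global_params, dtype=float)
    updates: list[ClientUpdate] = []
    for client in clients:
        try:
            update = client.train(global_params.copy())
        except Exception as exc:  # abort, never aggregate a partial round
            raise RuntimeError(f"client {client.id!r} failed; round aborted") from exc
        if update.parameters.shape != global_params.shape:
            raise RuntimeError(f"client {client.id!r} returned mismatched parameters")
        updates.append(update)
    new_global = aggregate(strategy, state, global_params, updates)
    total = float(sum(u.n_samples for u in updates))
    log = RoundLog(
        round_index=state.round,
        client_sizes={c.id: u.n_samples for c, u in zip(clients, updates)},
        client_weights={c.id: u.n_samples / total for c, u in zip(clients, updates)},
        global_checksum=float(np.sum(new_global)),
    )
    return new_global, state, log


def run_federated_training(
    clients: Sequence[ClientNode],
    run_config: FLRunConfig,
    eval_dataset: CohortDataset | None = None,
    init_params: ModelParameters | None = None,
) -> tuple[ModelParameters, list[RoundLog]]:
    """Run ``n_rounds`` sequential rounds and return the final global model.

    Client RNGs are derived deterministically from the master seed, so a rerun
    with identical configs reproduces parameters and logs exactly.  When an
    evaluation dataset is supplied, per-round held-out metrics are logged and
    the best-round model is kept alongside the final one (``logs[i].eval_metrics``).
    """
    if not clients:
        raise ValueError("need at least one client")
    template = clients[0].config
    for c in clients:
        if (c.config.n_genes, c.config.g_hidden_width, c.config.n_features) != (
            template.n_genes,
            template.g_hidden_width,
            template.n_features,
        ):
            raise ValueError("all clients must share the model architecture")
        c.config = replace(c.config, epochs=run_config.local_epochs)

    if len({c.id for c in clients}) != len(clients):
        raise ValueError("client ids must be unique")
    for c in clients:
        c.rng = derive_client_rng(run_config.seed, c.id)

    if init_params is None:
        init_params = init_model(replace(template, seed=run_config.seed))
    global_vec = init_params.to_vector()
    state = AggregationState.zeros(global_vec.shape[0])
    logs: list[RoundLog] = []
    best_loss = np.inf
    for _ in range(run_config.n_rounds):
        global_vec, state, log = run_round(global_vec, clients, run_config.strategy, state)
        if eval_dataset is not None:
            params = ModelParameters.from_vector(
                global_vec, template.n_genes, template.g_hidden_width, template.n_features
            )
            scores = predict(params, eval_dataset)
            from .metrics import bce_of_scores, evaluate  # local import, avoids cycle

            report = evaluate(eval_dataset.labels, scores)
            log.eval_metrics = {
                "auc": report.auc,
                "auprc": report.auprc,
                "mcc": report.mcc,
                "bce": bce_of_scores(eval_dataset.labels, scores),
            }
            if run_config.early_stop and log.eval_metrics["bce"] >= best_loss:
                logs.append(log)
                break
            best_loss = min(best_loss, log.eval_metrics["bce"])
        logs.append(log)
    final = ModelParameters.from_vector(
        global_vec, template.n_genes, template.g_hidden_width, template.n_features
    )
    return final, logs
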