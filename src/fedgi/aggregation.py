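"""Server-side aggregation strategies merging per-client parameter updates.

All strategies operate on flat parameter vectors.  The pseudo-gradient of a
round is defined as ``weighted_mean(client parameters) - previous global``;
the adaptive strategies (adam / yogi / adagrad variants) apply server-side
first/second-moment updates to it, per coordinate.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "ClientUpdate",
    "AggregationState",
    "StrategyConfig",
    "STRATEGY_NAMES",
    "weighted_mean",
    "fedavg_step",
    "fedavgm_step",
    "fedopt_step",
    "aggregate",
]

STRATEGY_NAMES = ("fedavg", "fedavgm", "fedadam", "fedyogi", "fedadagrad")

_ADAPTIVE_VARIANT = {"fedadam": "adam", "fedyogi": "yogi", "fedadagrad": "adagrad"}


@dataclass(frozen=True)
class ClientUpdate:
    """One client's post-training parameters with its local sample count."""

    parameters: np.ndarray
    n_samples: int

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "parameters", np.asarray(self.parameters, dtype=float)
        )
        if self.parameters.ndim != 1:
            raise ValueError("client parameters must be a flat vector")
        if self.n_samples < 1:
            raise ValueError("n_samples must be positive")


@dataclass
class AggregationState:
    """Server-side optimizer buffers, one slot per model coordinate."""

    m: np.ndarray  # first moment (adaptive strategies)
    v: np.ndarray  # second moment (adaptive strategies); entries >= 0
    momentum: np.ndarray  # FedAvgM buffer
    round: int = 0

    @classmethod
    def zeros(cls, n_params: int, v0: float = 0.0) -> "AggregationState":
        return cls(
            m=np.zeros(n_params),
            v=np.full(n_params, float(v0)),
            momentum=np.zeros(n_params),
        )


@dataclass(frozen=True)
class StrategyConfig:
    """Named strategy plus its server hyperparameters.

    ``server_lr`` defaults to 1.0 for fedavg/fedavgm and 0.1 for the
    adaptive strategies when left unset.
    """

    name: str = "fedavg"
    server_lr: float | None = None
    momentum: float = 0.9  # FedAvgM beta
    beta1: float = 0.9
    beta2: float = 0.99
    tau: float = 1e-3

    def __post_init__(self) -> None:
        if self.name not in STRATEGY_NAMES:
            raise ValueError(f"unknown strategy {self.name!r}; choose from {STRATEGY_NAMES}")
        for b in (self.momentum, self.beta1, self.beta2):
            if not (0.0 <= b < 1.0):
                raise ValueError("momentum/beta parameters must be in [0, 1)")
        if self.tau <= 0:
            raise ValueError("tau must be > 0")
        if self.server_lr is not None and self.server_lr <= 0:
            raise ValueError("server_lr must be > 0")

    @property
    def eta(self) -> float:
        if self.server_lr is not None:
            return self.server_lr
        return 0.1 if self.name in _ADAPTIVE_VARIANT else 1.0


def weighted_mean(updates: Sequence[ClientUpdate]) -> np.ndarray:
    """Sample-count-weighted elementwise mean of client parameter vectors.

    Summation runs in a canonical content-derived order so the result is
    bit-identical under any permutation of the client list.
    """
    if not updates:
        raise ValueError("need at least one client update")
    dim = updates[0].parameters.shape[0]
    for u in updates:
        if u.parameters.shape[0] != dim:
            raise ValueError("client parameter vectors differ in length")
    canonical = sorted(
        updates,
        key=lambda u: (u.n_samples, hashlib.sha1(u.parameters.tobytes()).hexdigest()),
    )
    total = float(sum(u.n_samples for u in updates))
    out = np.zeros(dim)
    for u in canonical:
        out += (u.n_samples / total) * u.parameters
    return out


def _check_shape(prev_global: np.ndarray, updates: Sequence[ClientUpdate]) -> np.ndarray:
    prev_global = np.asarray(prev_global, dtype=float)
    if updates and prev_global.shape != updates[0].parameters.shape:
        raise ValueError("global model and client updates differ in shape")
    return prev_global


def fedavg_step(prev_global: np.ndarray, updates: Sequence[ClientUpdate]) -> np.ndarray:
    """Plain federated averaging; prev_global is used only for shape checks."""
    _check_shape(prev_global, updates)
    return weighted_mean(updates)


def fedavgm_step(
    state: AggregationState,
    prev_global: np.ndarray,
    updates: Sequence[ClientUpdate],
    beta: float,
    eta: float,
) -> np.ndarray:
    """Federated averaging with a server-side momentum buffer."""
    prev_global = _check_shape(prev_global, updates)
    mean = weighted_mean(updates)
    delta = mean - prev_global
    state.momentum = beta * state.momentum + delta
    state.round += 1
    if beta == 0.0 and eta == 1.0:
        # algebraically prev + delta == mean; return it directly so the
        # fedavg reduction holds bitwise, not just to rounding error
        return mean
    return prev_global + eta * state.momentum


def fedopt_step(
    state: AggregationState,
    prev_global: np.ndarray,
    updates: Sequence[ClientUpdate],
    variant: str,
    beta1: float,
    beta2: float,
    eta: float,
    tau: float,
) -> np.ndarray:
    """Adaptive server optimizer step on the round's pseudo-gradient.

    variant: 'adam' (EMA of squared pseudo-gradients), 'adagrad'
    (accumulated sum), or 'yogi' (sign-controlled additive update).
    """
    if variant not in ("adam", "yogi", "adagrad"):
        raise ValueError(f"unknown adaptive variant {variant!r}")
    prev_global = _check_shape(prev_global, updates)
    delta = weighted_mean(updates) - prev_global
    state.m = beta1 * state.m + (1.0 - beta1) * delta
    d2 = np.square(delta)
    if variant == "adagrad":
        state.v = state.v + d2
    elif variant == "adam":
        state.v = beta2 * state.v + (1.0 - beta2) * d2
    else:  # yogi
        state.v = state.v - (1.0 - beta2) * d2 * np.sign(state.v - d2)
    state.round += 1
    return prev_global + eta * state.m / (np.sqrt(state.v) + tau)


def aggregate(
    strategy: StrategyConfig,
    state: AggregationState,
    prev_global: np.ndarray,
    updates: Sequence[ClientUpdate],
) -> np.ndarray:
    """Dispatch one aggregation step by strategy name."""
    if strategy.name == "fedavg":
        state.round += 1
        return fedavg_step(prev_global, updates)
    if strategy.name == "fedavgm":
        return fedavgm_step(state, prev_global, updates, strategy.momentum, strategy.eta)
    return fedopt_step(
        state,
        prev_global,
        updates,
        _ADAPTIVE_VARIANT[strategy.name],
        strategy.beta1,
        strategy.beta2,
        strategy.eta,
        strategy.tau,
    )
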