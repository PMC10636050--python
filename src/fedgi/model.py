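"""Gene-modular neural network with a shared per-gene module.

A single small module G (input = per-gene feature vector, one hidden
LeakyReLU layer, scalar output) is applied with shared weights to every gene
column of a sample.  The per-gene scalars are concatenated, passed through
dropout (training only) and an affine read-out with a sigmoid, like a
logistic regression over gene summaries.  Training uses mini-batch RMSprop
on binary cross-entropy plus an L2 penalty on weights (biases excluded).

Implemented directly on numpy arrays with hand-derived gradients so that
training is exactly reproducible and cheap to gradient-check.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .encoding import CohortDataset

__all__ = [
    "ModelConfig",
    "ModelParameters",
    "leaky_relu",
    "init_model",
    "forward",
    "predict",
    "bce_loss",
    "loss_and_grad",
    "train_local",
]

N_GENE_FEATURES = 11  # class histogram (9) + intolerance + publication weight


@dataclass(frozen=True)
class ModelConfig:
    """Architecture and local-training hyperparameters."""

    n_genes: int
    n_features: int = N_GENE_FEATURES
    g_hidden_width: int = 32
    dropout_p: float = 0.1
    l2_lambda: float = 1.0
    learning_rate: float = 0.001
    epochs: int = 100
    batch_size: int = 3
    seed: int = 0
    rmsprop_alpha: float = 0.99
    rmsprop_eps: float = 1e-8

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.g_hidden_width < 1 or self.n_features < 1:
            raise ValueError("n_genes, n_features and g_hidden_width must be >= 1")
        if not (0.0 <= self.dropout_p < 1.0):
            raise ValueError("dropout_p must be in [0, 1)")
        if self.l2_lambda < 0 or self.learning_rate <= 0:
            raise ValueError("l2_lambda must be >= 0 and learning_rate > 0")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")


@dataclass
class ModelParameters:
    """All trainable weights, addressable as a flat vector in a stable order.

    Flat ordering: ``W1, b1, w2, b2, w_out, b_out``.  ``W1/b1/w2/b2`` form
    the shared gene module G; its size is independent of ``n_genes``.
    """

    W1: np.ndarray  # (hidden, n_features)
    b1: np.ndarray  # (hidden,)
    w2: np.ndarray  # (hidden,)
    b2: float
    w_out: np.ndarray  # (n_genes,)
    b_out: float

    @property
    def n_genes(self) -> int:
        return self.w_out.shape[0]

    @property
    def hidden(self) -> int:
        return self.W1.shape[0]

    @property
    def n_features(self) -> int:
        return self.W1.shape[1]

    @property
    def g_module_size(self) -> int:
        return self.W1.size + self.b1.size + self.w2.size + 1

    @property
    def n_params(self) -> int:
        return self.g_module_size + self.n_genes + 1

    def to_vector(self) -> np.ndarray:
        return np.concatenate(
            [
                self.W1.ravel(),
                self.b1,
                self.w2,
                [self.b2],
                self.w_out,
                [self.b_out],
            ]
        )

    @classmethod
    def from_vector(
        cls, vec: np.ndarray, n_genes: int, hidden: int, n_features: int = N_GENE_FEATURES
    ) -> "ModelParameters":
        vec = np.asarray(vec, dtype=float)
        expected = hidden * n_features + 2 * hidden + 1 + n_genes + 1
        if vec.shape != (expected,):
            raise ValueError(f"expected flat vector of length {expected}, got {vec.shape}")
        off = 0

        def take(n: int) -> np.ndarray:
            nonlocal off
            out = vec[off : off + n]
            off += n
            return out

        W1 = take(hidden * n_features).reshape(hidden, n_features).copy()
        b1 = take(hidden).copy()
        w2 = take(hidden).copy()
        b2 = float(take(1)[0])
        w_out = take(n_genes).copy()
        b_out = float(take(1)[0])
        return cls(W1, b1, w2, b2, w_out, b_out)

    def copy(self) -> "ModelParameters":
        return ModelParameters(
            self.W1.copy(), self.b1.copy(), self.w2.copy(), self.b2,
            self.w_out.copy(), self.b_out,
        )

    def save(self, path: str | Path, config: ModelConfig | None = None) -> None:
        """Checkpoint as JSON (flat vector + shape metadata)."""
        payload = {
            "n_genes": self.n_genes,
            "hidden": self.hidden,
            "n_features": self.n_features,
            "vector": self.to_vector().tolist(),
        }
        if config is not None:
            payload["config"] = {
                k: getattr(config, k) for k in ModelConfig.__dataclass_fields__
            }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "ModelParameters":
        payload = json.loads(Path(path).read_text())
        return cls.from_vector(
            np.array(payload["vector"]),
            payload["n_genes"],
            payload["hidden"],
            payload.get("n_features", N_GENE_FEATURES),
        )


def leaky_relu(x):
    """max(0.01*x, x), elementwise."""
    return np.maximum(0.01 * np.asarray(x, dtype=float), x)


def _leaky_relu_grad(x):
    return np.where(np.asarray(x) > 0, 1.0, 0.01)


def init_model(config: ModelConfig) -> ModelParameters:
    """Random initialization, reproducible under ``config.seed``.

    Weights use uniform He-style fan-in scaling; biases start at zero.
    """
    rng = np.random.default_rng(config.seed)
    h, f, g = config.g_hidden_width, config.n_features, config.n_genes

    def u(shape, fan_in):
        bound = np.sqrt(1.0 / fan_in)
        return rng.uniform(-bound, bound, size=shape)

    return ModelParameters(
        W1=u((h, f), f),
        b1=np.zeros(h),
        w2=u(h, h),
        b2=0.0,
        w_out=u(g, g),
        b_out=0.0,
    )


def _forward_cache(params: ModelParameters, X: np.ndarray, drop_mask: np.ndarray | None):
    """Vectorized forward pass over a batch.

    X: (B, n_features, n_genes).  drop_mask: (B, n_genes) inverted-dropout
    multiplier (already scaled by 1/(1-p)) or None in evaluation mode.
    """
    Xt = np.transpose(X, (0, 2, 1))  # (B, G, F)
    z1 = Xt @ params.W1.T + params.b1  # (B, G, H)
    h1 = leaky_relu(z1)
    latent = h1 @ params.w2 + params.b2  # (B, G) per-gene scalar summaries
    dropped = latent if drop_mask is None else latent * drop_mask
    logits = dropped @ params.w_out + params.b_out  # (B,)
    prob = 1.0 / (1.0 + np.exp(-logits))
    return prob, (Xt, z1, h1, latent, dropped)


def forward(
    params: ModelParameters,
    sample: np.ndarray,
    training_mode: bool = False,
    dropout_p: float = 0.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray | float:
    """Predicted case probability for one sample (F, G) or a batch (B, F, G).

    Dropout on the concatenated per-gene latent vector is applied only in
    training mode (inverted scaling, so evaluation needs no rescale).
    """
    X = np.asarray(sample, dtype=float)
    single = X.ndim == 2
    if single:
        X = X[None]
    if X.ndim != 3 or X.shape[1] != params.n_features or X.shape[2] != params.n_genes:
        raise ValueError(
            f"expected sample of shape (B, {params.n_features}, {params.n_genes}), "
            f"got {X.shape}"
        )
    mask = None
    if training_mode and dropout_p > 0.0:
        if rng is None:
            raise ValueError("training-mode dropout requires an rng")
        keep = rng.random((X.shape[0], params.n_genes)) >= dropout_p
        mask = keep / (1.0 - dropout_p)
    prob, _ = _forward_cache(params, X, mask)
    return float(prob[0]) if single else prob


def predict(params: ModelParameters, dataset_or_tensor) -> np.ndarray:
    """Deterministic evaluation-mode scores for a cohort or raw tensor."""
    X = getattr(dataset_or_tensor, "tensor", dataset_or_tensor)
    return forward(params, np.asarray(X, dtype=float))


_EPS = 1e-12


def bce_loss(prediction, label) -> float:
    """Binary cross-entropy, mean over elements, clamped away from {0,1}."""
    p = np.clip(np.asarray(prediction, dtype=float), _EPS, 1.0 - _EPS)
    y = np.asarray(label, dtype=float)
    return float(np.mean(-(y * np.log(p) + (1.0 - y) * np.log(1.0 - p))))


def _l2_penalty(params: ModelParameters, lam: float) -> float:
    if lam == 0.0:
        return 0.0
    return lam * float(
        np.sum(params.W1**2) + np.sum(params.w2**2) + np.sum(params.w_out**2)
    )


def loss_and_grad(
    params: ModelParameters,
    X: np.ndarray,
    y: np.ndarray,
    l2_lambda: float = 0.0,
    drop_mask: np.ndarray | None = None,
) -> tuple[float, ModelParameters]:
    """Mean BCE + L2 over a batch and its analytic gradient.

    The gradient is returned as a ``ModelParameters`` holding per-field
    derivatives.  Biases are excluded from the L2 penalty.
    """
    B = X.shape[0]
    prob, (Xt, z1, h1, latent, dropped) = _forward_cache(params, X, drop_mask)
    loss = bce_loss(prob, y) + _l2_penalty(params, l2_lambda)

    dlogits = (prob - y) / B  # (B,)
    gw_out = dropped.T @ dlogits
    gb_out = float(dlogits.sum())
    ddropped = np.outer(dlogits, params.w_out)  # (B, G)
    dlatent = ddropped if drop_mask is None else ddropped * drop_mask
    gw2 = np.einsum("bg,bgh->h", dlatent, h1)
    gb2 = float(dlatent.sum())
    dz1 = dlatent[..., None] * params.w2 * _leaky_relu_grad(z1)  # (B, G, H)
    gW1 = np.einsum("bgh,bgf->hf", dz1, Xt)
    gb1 = dz1.sum(axis=(0, 1))
    if l2_lambda:
        gW1 = gW1 + 2.0 * l2_lambda * params.W1
        gw2 = gw2 + 2.0 * l2_lambda * params.w2
        gw_out = gw_out + 2.0 * l2_lambda * params.w_out
    return loss, ModelParameters(gW1, gb1, gw2, gb2, gw_out, gb_out)


@dataclass
class _RMSPropState:
    """Per-field running mean of squared gradients; fresh per training call."""

    v: ModelParameters
    alpha: float
    eps: float
    lr: float

    @classmethod
    def fresh(cls, params: ModelParameters, config: ModelConfig) -> "_RMSPropState":
        zeros = ModelParameters(
            np.zeros_like(params.W1), np.zeros_like(params.b1),
            np.zeros_like(params.w2), 0.0, np.zeros_like(params.w_out), 0.0,
        )
        return cls(zeros, config.rmsprop_alpha, config.rmsprop_eps, config.learning_rate)

    def step(self, params: ModelParameters, grad: ModelParameters) -> None:
        for name in ("W1", "b1", "w2", "b2", "w_out", "b_out"):
            g = getattr(grad, name)
            v = getattr(self.v, name)
            v_new = self.alpha * v + (1.0 - self.alpha) * np.square(g)
            setattr(self.v, name, v_new)
            update = self.lr * g / (np.sqrt(v_new) + self.eps)
            setattr(params, name, getattr(params, name) - update)


def train_local(
    params: ModelParameters,
    dataset: "CohortDataset",
    config: ModelConfig,
    rng: np.random.Generator | None = None,
) -> tuple[ModelParameters, list[float]]:
    """Mini-batch RMSprop training on one local dataset.

    Starts from a copy of ``params`` with a fresh optimizer state.  Each
    epoch shuffles the sample order under ``rng`` (derived from
    ``config.seed`` when not given); the incomplete final batch is used
    as-is.  Returns the trained parameters and the per-epoch mean loss
    (BCE + L2) trace.
    """
    if dataset.n_samples == 0:
        raise ValueError("dataset must be non-empty")
    y_all = np.asarray(dataset.labels, dtype=float)
    if len(np.unique(y_all)) < 2:
        warnings.warn(
            f"dataset {dataset.center_id!r} contains a single class; "
            "training proceeds", stacklevel=2,
        )
    if rng is None:
        rng = np.random.default_rng(config.seed)
    params = params.copy()
    opt = _RMSPropState.fresh(params, config)
    X_all = dataset.tensor
    n = dataset.n_samples
    trace: list[float] = []
    for _ in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            X, y = X_all[idx], y_all[idx]
            mask = None
            if config.dropout_p > 0.0:
                keep = rng.random((len(idx), params.n_genes)) >= config.dropout_p
                mask = keep / (1.0 - config.dropout_p)
            loss, grad = loss_and_grad(params, X, y, config.l2_lambda, mask)
            opt.step(params, grad)
            epoch_loss += loss
            n_batches += 1
        trace.append(epoch_loss / n_batches)
    return params, trace


def training_config_for(dataset: "CohortDataset", **overrides) -> ModelConfig:
    """Convenience constructor inferring tensor shape from a cohort."""
    base = dict(n_genes=dataset.n_genes, n_features=dataset.tensor.shape[1])
    base.update(overrides)
    return ModelConfig(**base)
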