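"""Semi-supervised GCN: stacked graph-learning blocks trained transductively.

The model is a stack of L graph-learning blocks on the cohort graph.  Each
layer applies the renormalized propagation rule

    H^{l+1} = S H^l W^l,        S = D~^{-1/2} (A + I) D~^{-1/2},

with H^0 = X.  The first L-1 blocks are graph conv -> batch norm -> ReLU
-> dropout with k graph filters each; the final block is graph conv (to 2
output channels) -> batch norm -> softmax over the two risk classes.

Training is transductive full-graph gradient descent: every forward pass
uses all nodes' features (labeled, unlabeled, and test), but the loss is a
masked (optionally inverse-frequency-weighted) cross-entropy over training
nodes only, optimized with Adam.  The whole engine is plain numpy with
hand-derived gradients; correctness is pinned by a finite-difference
gradient check and a per-node aggregation oracle in the test suite.

Class encoding is positive = 1 (high risk, probability column 1) and
negative = 0 (column 0) throughout.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .graph import PopulationGraph

logger = logging.getLogger(__name__)

#: Published hyperparameter search grids.
LAYER_GRID = (1, 2, 3, 4)
FILTER_GRID = (512, 256, 128, 64, 32, 16)

_BN_EPS = 1e-5
_BN_MOMENTUM = 0.1  # fraction of the batch moment merged into the running moment
_ADAM_EPS = 1e-8
_PROB_CLAMP = 1e-12
_CHECKPOINT_FORMAT = 1


class GCNError(ValueError):
    """Invalid model configuration or training input."""


@dataclass
class GCNConfig:
    """Architecture and optimization settings.

    Defaults reproduce the published optimum for the motor-outcome task:
    three graph-learning blocks of 128 filters, dropout 0.5, weighted
    cross-entropy, Adam(lr=0.01, betas=(0.9, 0.999)), at most 2000 epochs.
    ``patience`` enables an optional early stop when the training loss has
    not improved for that many epochs; it is off (None) by default.
    """

    n_layers: int = 3
    n_filters: int = 128
    dropout_rate: float = 0.5
    learning_rate: float = 0.01
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    max_epochs: int = 2000
    loss: str = "weighted"
    seed: int = 0
    patience: int | None = None

    def __post_init__(self) -> None:
        if self.n_layers not in LAYER_GRID:
            raise GCNError(f"n_layers must be one of {LAYER_GRID}, got {self.n_layers}")
        if self.n_filters < 1:
            raise GCNError(f"n_filters must be positive, got {self.n_filters}")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise GCNError(f"dropout_rate must be in [0, 1), got {self.dropout_rate}")
        if self.learning_rate <= 0:
            raise GCNError(f"learning_rate must be positive, got {self.learning_rate}")
        if self.max_epochs < 1:
            raise GCNError(f"max_epochs must be positive, got {self.max_epochs}")
        if self.loss not in ("weighted", "unweighted"):
            raise GCNError(f"loss must be 'weighted' or 'unweighted', got {self.loss!r}")


class GCNModel:
    """Layer weights and batch-norm state for a stack of graph-learning blocks."""

    def __init__(self, config: GCNConfig, n_features: int):
        self.config = config
        self.n_features = int(n_features)
        dims = [self.n_features] + [config.n_filters] * (config.n_layers - 1) + [2]
        self.dims = dims
        self.weights: list[np.ndarray] = []
        self.gamma: list[np.ndarray] = []
        self.beta: list[np.ndarray] = []
        self.running_mean: list[np.ndarray] = []
        self.running_var: list[np.ndarray] = []
        for d_in, d_out in zip(dims[:-1], dims[1:]):
            self.weights.append(np.zeros((d_in, d_out)))
            self.gamma.append(np.ones(d_out))
            self.beta.append(np.zeros(d_out))
            self.running_mean.append(np.zeros(d_out))
            self.running_var.append(np.ones(d_out))

    @classmethod
    def initialize(cls, config: GCNConfig, n_features: int, rng: np.random.Generator) -> "GCNModel":
        """Glorot-uniform weight init; batch norm starts as the identity."""
        model = cls(config, n_features)
        for l, (d_in, d_out) in enumerate(zip(model.dims[:-1], model.dims[1:])):
            limit = np.sqrt(6.0 / (d_in + d_out))
            model.weights[l] = rng.uniform(-limit, limit, size=(d_in, d_out))
        return model

    @property
    def n_layers(self) -> int:
        return self.config.n_layers

    def trainable_parameters(self) -> list[np.ndarray]:
        params: list[np.ndarray] = []
        for l in range(self.n_layers):
            params += [self.weights[l], self.gamma[l], self.beta[l]]
        return params


def _softmax(Z: np.ndarray) -> np.ndarray:
    Z = Z - Z.max(axis=1, keepdims=True)
    e = np.exp(Z)
    return e / e.sum(axis=1, keepdims=True)


def _forward(
    model: GCNModel,
    graph: PopulationGraph,
    training_mode: bool,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, dict]:
    """Full-graph forward pass; returns (probabilities, cache for backprop)."""
    if graph.X.shape[1] != model.n_features:
        raise GCNError(
            f"layer 0: model expects {model.n_features} input features, "
            f"graph provides {graph.X.shape[1]}"
        )
    if training_mode and model.config.dropout_rate > 0 and rng is None:
        raise GCNError("training-mode forward with dropout requires an rng")
    S = graph.S
    H = graph.X
    L = model.n_layers
    cache: dict = {"H_in": [], "Z": [], "Zhat": [], "ivar": [], "Y": [], "drop": []}
    for l in range(L):
        W = model.weights[l]
        if H.shape[1] != W.shape[0]:
            raise GCNError(f"layer {l}: shapes {H.shape} x {W.shape} do not align")
        SH = S @ H
        Z = SH @ W
        if training_mode:
            mu = Z.mean(axis=0)
            var = Z.var(axis=0)
            model.running_mean[l] = (1 - _BN_MOMENTUM) * model.running_mean[l] + _BN_MOMENTUM * mu
            model.running_var[l] = (1 - _BN_MOMENTUM) * model.running_var[l] + _BN_MOMENTUM * var
        else:
            mu = model.running_mean[l]
            var = model.running_var[l]
        ivar = 1.0 / np.sqrt(var + _BN_EPS)
        Zhat = (Z - mu) * ivar
        Y = model.gamma[l] * Zhat + model.beta[l]
        cache["H_in"].append(H)
        cache["Z"].append(Z)
        cache["Zhat"].append(Zhat)
        cache["ivar"].append(ivar)
        cache["Y"].append(Y)
        if l < L - 1:
            H = np.maximum(Y, 0.0)
            if training_mode and model.config.dropout_rate > 0:
                keep = 1.0 - model.config.dropout_rate
                mask = (rng.random(H.shape) < keep) / keep
                H = H * mask
                cache["drop"].append(mask)
            else:
                cache["drop"].append(None)
        else:
            P = _softmax(Y)
    cache["P"] = P
    cache["training_mode"] = training_mode
    return P, cache


def forward(
    model: GCNModel,
    graph: PopulationGraph,
    training_mode: bool = False,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """N x 2 class probabilities for every node; rows sum to 1."""
    P, _ = _forward(model, graph, training_mode, rng)
    return P


def class_weights(y: np.ndarray, train_mask: np.ndarray) -> dict[int, float]:
    """Inverse-frequency weights beta_c = N_mask / C_c from training-mask counts."""
    y_m = np.asarray(y)[np.asarray(train_mask, dtype=bool)]
    if y_m.size == 0:
        raise GCNError("training mask is empty")
    if np.any(y_m < 0):
        raise GCNError("training mask selects a node with missing label")
    n = y_m.size
    counts = {c: int((y_m == c).sum()) for c in (0, 1)}
    if counts[0] == 0 or counts[1] == 0:
        raise GCNError("training mask contains a single class; cannot fit inverse-frequency weights")
    return {c: n / counts[c] for c in (0, 1)}


def weighted_loss(
    probabilities: np.ndarray,
    y: np.ndarray,
    train_mask: np.ndarray,
    mode: str = "weighted",
) -> float:
    """Masked cross-entropy: mean over training nodes of -beta_i log p(y_i).

    ``weighted`` uses inverse-frequency class weights beta_i = N_mask / C_class(i)
    computed on the training mask; ``unweighted`` sets beta_i = 1.
    Probabilities are clamped at 1e-12 inside the log.
    """
    if mode not in ("weighted", "unweighted"):
        raise GCNError(f"unknown loss mode {mode!r}")
    mask = np.asarray(train_mask, dtype=bool)
    y = np.asarray(y)
    P = np.asarray(probabilities, dtype=float)
    y_m = y[mask]
    if y_m.size == 0:
        raise GCNError("training mask is empty")
    if np.any(y_m < 0):
        raise GCNError("training mask selects a node with missing label")
    if mode == "weighted":
        beta = class_weights(y, mask)
        b = np.where(y_m == 1, beta[1], beta[0])
    else:
        b = np.ones(y_m.size)
    p_true = P[mask, y_m]
    if np.any(p_true <= _PROB_CLAMP) or np.any(p_true >= 1 - _PROB_CLAMP):
        logger.debug("probabilities clamped to [%g, %g] inside the log", _PROB_CLAMP, 1 - _PROB_CLAMP)
    p_true = np.clip(p_true, _PROB_CLAMP, 1.0)
    return float(np.mean(-b * np.log(p_true)))


def _bn_backward(dY, Zhat, ivar, gamma):
    n = dY.shape[0]
    dgamma = (dY * Zhat).sum(axis=0)
    dbeta = dY.sum(axis=0)
    dZhat = dY * gamma
    dZ = (ivar / n) * (n * dZhat - dZhat.sum(axis=0) - Zhat * (dZhat * Zhat).sum(axis=0))
    return dZ, dgamma, dbeta


def _backward(
    model: GCNModel,
    graph: PopulationGraph,
    cache: dict,
    y: np.ndarray,
    train_mask: np.ndarray,
    beta_by_class: dict[int, float] | None,
) -> list[np.ndarray]:
    """Gradients of the masked (weighted) cross-entropy w.r.t. trainable params.

    Returns gradients in the order of :meth:`GCNModel.trainable_parameters`.
    Only training-mask rows receive a loss gradient, so non-training nodes'
    labels contribute exactly zero.
    """
    S = graph.S
    L = model.n_layers
    P = cache["P"]
    mask = np.asarray(train_mask, dtype=bool)
    y_m = y[mask]
    n_mask = int(mask.sum())
    if beta_by_class is None:
        b = np.ones(n_mask)
    else:
        b = np.where(y_m == 1, beta_by_class[1], beta_by_class[0])
    # d loss / d (softmax input) on masked rows: beta_i (p - onehot) / N_mask
    dY = np.zeros_like(P)
    G = P[mask].copy()
    G[np.arange(n_mask), y_m] -= 1.0
    dY[mask] = (b / n_mask)[:, None] * G

    grads: list[np.ndarray | None] = [None] * (3 * L)
    for l in range(L - 1, -1, -1):
        dZ, dgamma, dbeta = _bn_backward(dY, cache["Zhat"][l], cache["ivar"][l], model.gamma[l])
        H_in = cache["H_in"][l]
        dW = (S @ H_in).T @ dZ
        grads[3 * l] = dW
        grads[3 * l + 1] = dgamma
        grads[3 * l + 2] = dbeta
        if l > 0:
            dH = S.T @ (dZ @ model.weights[l].T)
            drop = cache["drop"][l - 1]
            if drop is not None:
                dH = dH * drop
            dY = dH * (cache["Y"][l - 1] > 0)
    return grads  # type: ignore[return-value]


def _calibrate_batch_norm(model: GCNModel, graph: PopulationGraph) -> None:
    """Set running batch-norm moments to the full-graph statistics at the final weights.

    During training the running moments trail the continually-updated
    weights; on a dense cohort graph the propagation operator is close to a
    global average, per-channel variances across nodes are small, and batch
    norm amplifies that lag.  In transductive full-graph training the
    evaluation batch is the training batch, so the exact moments are
    available: one dropout-free pass recomputes them layer by layer.
    """
    H = graph.X
    S = graph.S
    for l in range(model.n_layers):
        Z = S @ H @ model.weights[l]
        mu = Z.mean(axis=0)
        var = Z.var(axis=0)
        model.running_mean[l] = mu
        model.running_var[l] = var
        Y = model.gamma[l] * (Z - mu) / np.sqrt(var + _BN_EPS) + model.beta[l]
        if l < model.n_layers - 1:
            H = np.maximum(Y, 0.0)


@dataclass
class TrainingResult:
    """Trained model, per-epoch loss trajectory, and full-graph probabilities."""

    model: GCNModel
    loss_trajectory: np.ndarray
    probabilities: np.ndarray

    def __post_init__(self) -> None:
        self.loss_trajectory = np.asarray(self.loss_trajectory, dtype=float)
        rows = self.probabilities.sum(axis=1)
        if np.abs(rows - 1.0).max() > 1e-6:
            raise GCNError("probability rows do not sum to 1")


def train(graph: PopulationGraph, config: GCNConfig) -> TrainingResult:
    """Masked transductive training of the GCN on the full cohort graph.

    Every epoch runs a full-graph forward pass (all nodes' features mix
    through S), computes the loss on ``train_labeled`` nodes only, and takes
    one Adam step.  Deterministic given ``config.seed``.  After training the
    returned probabilities come from an evaluation-mode forward pass
    (running batch-norm moments, no dropout).
    """
    mask = graph.masks["train_labeled"]
    y = graph.y
    beta = class_weights(y, mask)  # validates both classes present
    beta_by_class = beta if config.loss == "weighted" else None

    rng = np.random.default_rng(config.seed)
    model = GCNModel.initialize(config, graph.n_features, rng)
    params = model.trainable_parameters()
    m_state = [np.zeros_like(p) for p in params]
    v_state = [np.zeros_like(p) for p in params]
    b1, b2, lr = config.adam_beta1, config.adam_beta2, config.learning_rate

    trajectory: list[float] = []
    best = np.inf
    stale = 0
    for epoch in range(1, config.max_epochs + 1):
        P, cache = _forward(model, graph, training_mode=True, rng=rng)
        loss = weighted_loss(P, y, mask, mode=config.loss)
        trajectory.append(loss)
        grads = _backward(model, graph, cache, y, mask, beta_by_class)
        for p, g, m_s, v_s in zip(params, grads, m_state, v_state):
            m_s *= b1
            m_s += (1 - b1) * g
            v_s *= b2
            v_s += (1 - b2) * g * g
            m_hat = m_s / (1 - b1**epoch)
            v_hat = v_s / (1 - b2**epoch)
            p -= lr * m_hat / (np.sqrt(v_hat) + _ADAM_EPS)
        if config.patience is not None:
            if loss < best - 1e-6:
                best = loss
                stale = 0
            else:
                stale += 1
                if stale >= config.patience:
                    logger.info("early stop at epoch %d (loss %.6f)", epoch, loss)
                    break

    _calibrate_batch_norm(model, graph)
    probabilities = forward(model, graph, training_mode=False)
    return TrainingResult(model, np.array(trajectory), probabilities)


def predict(
    result: TrainingResult, node_mask: np.ndarray | Sequence[int]
) -> tuple[np.ndarray, np.ndarray]:
    """Labels and positive-class probabilities for the selected nodes.

    The label is the argmax of the two-class row; an exact tie goes to the
    positive (high-risk) class.
    """
    P = result.probabilities
    node_mask = np.asarray(node_mask)
    if node_mask.dtype == bool:
        if node_mask.size != P.shape[0]:
            raise GCNError("boolean node mask length does not match the graph")
        rows = P[node_mask]
    else:
        if node_mask.size and (node_mask.min() < 0 or node_mask.max() >= P.shape[0]):
            raise GCNError("node index out of range")
        rows = P[node_mask]
    pos = rows[:, 1]
    labels = (pos >= rows[:, 0]).astype(int)
    return labels, pos


def save_checkpoint(
    model: GCNModel,
    path: str | Path,
    node_ids: Sequence[str] | None = None,
    sigma: float | None = None,
    kernel: str | None = None,
) -> None:
    """Serialize config + all weights (and graph provenance) to one .npz file."""
    path = Path(path)
    meta = {
        "format": _CHECKPOINT_FORMAT,
        "config": asdict(model.config),
        "n_features": model.n_features,
        "sigma": sigma,
        "kernel": kernel,
    }
    arrays = {"meta_json": np.array(json.dumps(meta))}
    if node_ids is not None:
        arrays["node_ids"] = np.array(list(node_ids))
    for l in range(model.n_layers):
        arrays[f"W_{l}"] = model.weights[l]
        arrays[f"gamma_{l}"] = model.gamma[l]
        arrays[f"beta_{l}"] = model.beta[l]
        arrays[f"running_mean_{l}"] = model.running_mean[l]
        arrays[f"running_var_{l}"] = model.running_var[l]
    np.savez(path, **arrays)


def load_checkpoint(path: str | Path) -> tuple[GCNModel, dict]:
    """Inverse of :func:`save_checkpoint`; returns (model, metadata)."""
    with np.load(Path(path), allow_pickle=False) as data:
        meta = json.loads(str(data["meta_json"]))
        if meta.get("format") != _CHECKPOINT_FORMAT:
            raise GCNError(f"unsupported checkpoint format: {meta.get('format')}")
        config = GCNConfig(**meta["config"])
        model = GCNModel(config, meta["n_features"])
        for l in range(model.n_layers):
            model.weights[l] = data[f"W_{l}"]
            model.gamma[l] = data[f"gamma_{l}"]
            model.beta[l] = data[f"beta_{l}"]
            model.running_mean[l] = data[f"running_mean_{l}"]
            model.running_var[l] = data[f"running_var_{l}"]
        if "node_ids" in data:
            meta["node_ids"] = [str(s) for s in data["node_ids"]]
    return model, meta
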