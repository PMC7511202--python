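"""Fully-connected feedforward networks with per-layer intrinsic mechanisms.

Training follows a five-step loop per batch: feedforward (caching every
intermediate), intrinsic parameter update from the cached batch statistics,
then a synaptic weight update by backpropagation with Adam on a softmax
cross-entropy loss. The intrinsic parameters are treated as constants of the
forward pass during backprop (``du/dx = 1/a`` for IP/BN, ``alpha`` for
Infomax); they are governed solely by their local rule, never by the error
gradient.

Layer convention: every non-output layer (including the input layer) applies
its rule's tanh transform to its input, then feeds ``W @ y + B``; the output
layer applies a ReLU to its pre-activation, and the loss takes a softmax over
those ReLU outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Literal, Optional

import h5py
import numpy as np
import pandas as pd

from .data import TrainingBatch
from .rules import (
    IPState,
    IncrementalBNState,
    InfomaxState,
    IntrinsicLearningRates,
    RuleState,
    bn_transform,
    bn_update,
    compute_batch_stats,
    infomax_transform,
    infomax_update,
    ip_transform,
    ip_update,
)

__all__ = [
    "RULE_KINDS",
    "LayerParams",
    "NetworkModel",
    "ForwardCache",
    "TrainConfig",
    "TrainingRecord",
    "AdamOptimizer",
    "init_network",
    "forward_pass",
    "intrinsic_step",
    "loss_and_grads",
    "weight_step",
    "train",
    "save_checkpoint",
    "load_checkpoint",
]

RuleKind = Literal["ip", "infomax", "bn_incremental", "standard"]
RULE_KINDS = ("ip", "infomax", "bn_incremental", "standard")


@dataclass
class LayerParams:
    """Weights leaving one non-output layer, plus that layer's rule state.

    ``W`` has shape (next_dim, this_dim); ``rule_state`` is None for
    standard networks (plain ``tanh``).
    """

    W: np.ndarray
    B_add: np.ndarray
    rule_state: Optional[RuleState] = None


@dataclass
class NetworkModel:
    layers: list[LayerParams]
    layer_sizes: list[int]
    rule_kind: RuleKind


@dataclass
class ForwardCache:
    """All intermediates of one feedforward pass, batch-major.

    ``x[l]``, ``u[l]``, ``y[l]`` are the input, normalised pre-activation and
    tanh output of non-output layer ``l``; ``z_out`` is the output layer's
    pre-activation, ``y_out = relu(z_out)``. ``du_dx[l]`` caches the
    transform derivative used by backprop, frozen at forward time so a
    subsequent intrinsic update cannot alter this batch's gradients.
    """

    x: list[np.ndarray]
    u: list[np.ndarray]
    y: list[np.ndarray]
    du_dx: list[np.ndarray]
    z_out: np.ndarray
    y_out: np.ndarray


@dataclass
class TrainConfig:
    synaptic_lr: float = 0.03
    intrinsic_eta: float = 1e-4
    batch_size: int = 64
    epochs: int = 1
    seed: int = 0
    loss: str = "cross_entropy"
    optimizer: str = "adam"

    def __post_init__(self) -> None:
        if self.synaptic_lr < 0:
            raise ValueError("synaptic_lr must be >= 0")
        if self.intrinsic_eta < 0:
            raise ValueError("intrinsic_eta must be >= 0")
        if self.batch_size < 1 or self.epochs < 0:
            raise ValueError("batch_size >= 1 and epochs >= 0 required")
        if self.loss != "cross_entropy":
            raise ValueError("only cross_entropy loss is supported")
        if self.optimizer != "adam":
            raise ValueError("only adam is supported")


@dataclass
class TrainingRecord:
    """Per-epoch mean losses of one run."""

    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    diverged: bool = False

    def to_frame(self, run_id: str = "run", seed: int | None = None) -> pd.DataFrame:
        rows = [
            {"run_id": run_id, "seed": seed, "epoch": e, "split": "train", "loss": v}
            for e, v in enumerate(self.train_loss)
        ]
        rows += [
            {"run_id": run_id, "seed": seed, "epoch": e, "split": "val", "loss": v}
            for e, v in enumerate(self.val_loss)
        ]
        return pd.DataFrame(rows, columns=["run_id", "seed", "epoch", "split", "loss"])


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------

def init_network(layer_sizes: list[int], rule_kind: RuleKind, seed: int) -> NetworkModel:
    """Seeded network with uniform fan-in weights (+-1/sqrt(n_in)), additive
    biases at zero, and fresh rule states (a=1, b=0 / alpha=1, beta=0) on
    every non-output layer."""
    if rule_kind not in RULE_KINDS:
        raise ValueError(f"rule_kind must be one of {RULE_KINDS}")
    sizes = [int(s) for s in layer_sizes]
    if len(sizes) < 3:
        raise ValueError("need at least input, one hidden, and output sizes")
    if any(s < 1 for s in sizes):
        raise ValueError("all layer sizes must be >= 1")
    rng = np.random.default_rng(seed)
    layers = []
    for n_in, n_out in zip(sizes[:-1], sizes[1:]):
        limit = 1.0 / np.sqrt(n_in)
        W = rng.uniform(-limit, limit, size=(n_out, n_in))
        B = np.zeros(n_out)
        if rule_kind == "ip":
            state: Optional[RuleState] = IPState.initial(n_in)
        elif rule_kind == "infomax":
            state = InfomaxState.initial(n_in)
        elif rule_kind == "bn_incremental":
            state = IncrementalBNState.initial(n_in)
        else:
            state = None
        layers.append(LayerParams(W=W, B_add=B, rule_state=state))
    return NetworkModel(layers=layers, layer_sizes=sizes, rule_kind=rule_kind)


# ---------------------------------------------------------------------------
# forward
# ---------------------------------------------------------------------------

def _apply_rule(x: np.ndarray, layer: LayerParams) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return (u, y, du/dx) for one non-output layer."""
    state = layer.rule_state
    if state is None:  # standard: plain tanh
        y = np.tanh(x)
        return x, y, np.ones(x.shape[-1])
    if isinstance(state, IPState):
        y, u = ip_transform(x, state, return_u=True)
        return u, y, 1.0 / state.a
    if isinstance(state, InfomaxState):
        y, u = infomax_transform(x, state, return_u=True)
        return u, y, np.broadcast_to(np.asarray(state.alpha, dtype=float), x.shape[-1:]).copy()
    y, u = bn_transform(x, state, return_u=True)
    return u, y, 1.0 / state.a_bn


def forward_pass(model: NetworkModel, batch: TrainingBatch | np.ndarray) -> ForwardCache:
    """Feedforward pass caching every intermediate for stats and backprop."""
    x = batch.inputs if isinstance(batch, TrainingBatch) else np.asarray(batch, dtype=float)
    if x.ndim != 2 or x.shape[1] != model.layer_sizes[0]:
        raise ValueError(
            f"input shape {x.shape} incompatible with input dimension {model.layer_sizes[0]}"
        )
    xs, us, ys, duds = [], [], [], []
    for l, layer in enumerate(model.layers):
        if not np.all(np.isfinite(x)):
            raise FloatingPointError(f"non-finite activations entering layer {l}")
        u, y, du_dx = _apply_rule(x, layer)
        xs.append(x)
        us.append(u)
        ys.append(y)
        duds.append(du_dx)
        x = y @ layer.W.T + layer.B_add
    if not np.all(np.isfinite(x)):
        raise FloatingPointError("non-finite activations at the output layer")
    return ForwardCache(x=xs, u=us, y=ys, du_dx=duds, z_out=x, y_out=np.maximum(x, 0.0))


# ---------------------------------------------------------------------------
# intrinsic step
# ---------------------------------------------------------------------------

def intrinsic_step(
    model: NetworkModel, cache: ForwardCache, rates: IntrinsicLearningRates
) -> NetworkModel:
    """Update every intrinsic neuron from its cached (x, y) batch statistics.

    The output layer carries no rule and is untouched; for a standard
    network this is a no-op. Infomax and incremental BN use the single rate
    ``rates.eta``; IP additionally uses the bias rate ``rates.eta_b``.
    """
    if model.rule_kind == "standard":
        return model
    for l, layer in enumerate(model.layers):
        stats = compute_batch_stats(cache.x[l], cache.y[l])
        state = layer.rule_state
        if isinstance(state, IPState):
            layer.rule_state = ip_update(state, stats, rates)
        elif isinstance(state, InfomaxState):
            layer.rule_state = infomax_update(state, stats, rates.eta)
        elif isinstance(state, IncrementalBNState):
            layer.rule_state = bn_update(state, stats, rates.eta)
    return model


# ---------------------------------------------------------------------------
# loss and backprop
# ---------------------------------------------------------------------------

def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def loss_and_grads(
    model: NetworkModel, cache: ForwardCache, batch: TrainingBatch
) -> tuple[float, list[tuple[np.ndarray, np.ndarray]]]:
    """Mean softmax cross-entropy on the ReLU outputs, with gradients for
    every (W, B_add).

    Gradients flow through the cached transform derivatives only; intrinsic
    parameters receive no error gradient.
    """
    t = batch.targets
    n = len(t)
    if np.any(t >= model.layer_sizes[-1]):
        raise ValueError("target label outside class count")
    p = _softmax(cache.y_out)
    loss = float(-np.mean(np.log(p[np.arange(n), t] + 1e-300)))

    g_yout = p.copy()
    g_yout[np.arange(n), t] -= 1.0
    g_yout /= n
    delta = g_yout * (cache.z_out > 0)  # through the output ReLU

    grads: list[tuple[np.ndarray, np.ndarray]] = [None] * len(model.layers)  # type: ignore
    for l in range(len(model.layers) - 1, -1, -1):
        layer = model.layers[l]
        y_l = cache.y[l]
        grads[l] = (delta.T @ y_l, delta.sum(axis=0))
        if l > 0:
            g_y = delta @ layer.W
            g_u = g_y * (1.0 - y_l * y_l)
            delta = g_u * cache.du_dx[l]
    return loss, grads


class AdamOptimizer:
    """Adam on the synaptic parameters (W, B_add) of a model.

    Standard moment estimates with bias correction; beta1=0.9, beta2=0.999,
    eps=1e-8 fixed.
    """

    def __init__(self, model: NetworkModel, lr: float, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [(np.zeros_like(l.W), np.zeros_like(l.B_add)) for l in model.layers]
        self.v = [(np.zeros_like(l.W), np.zeros_like(l.B_add)) for l in model.layers]

    def step(self, model: NetworkModel, grads: list[tuple[np.ndarray, np.ndarray]]) -> None:
        self.t += 1
        c1 = 1.0 - self.beta1**self.t
        c2 = 1.0 - self.beta2**self.t
        for l, layer in enumerate(model.layers):
            for j, (param, g) in enumerate([(layer.W, grads[l][0]), (layer.B_add, grads[l][1])]):
                m = self.m[l][j]
                v = self.v[l][j]
                m *= self.beta1
                m += (1.0 - self.beta1) * g
                v *= self.beta2
                v += (1.0 - self.beta2) * g * g
                param -= self.lr * (m / c1) / (np.sqrt(v / c2) + self.eps)


def weight_step(
    model: NetworkModel,
    cache: ForwardCache,
    batch: TrainingBatch,
    config: TrainConfig,
    optimizer: Optional[AdamOptimizer] = None,
) -> tuple[NetworkModel, float]:
    """One Adam step on the synaptic weights; returns the mean batch loss."""
    loss, grads = loss_and_grads(model, cache, batch)
    if not np.isfinite(loss):
        raise FloatingPointError("non-finite loss: training diverged")
    if optimizer is None:
        optimizer = AdamOptimizer(model, lr=config.synaptic_lr)
    optimizer.step(model, grads)
    return model, loss


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------

def evaluate_loss(model: NetworkModel, batch: TrainingBatch) -> float:
    """Mean loss on a dataset without any updates."""
    cache = forward_pass(model, batch)
    loss, _ = loss_and_grads(model, cache, batch)
    return loss


def train(
    model: NetworkModel,
    dataset: TrainingBatch,
    config: TrainConfig,
    val_dataset: Optional[TrainingBatch] = None,
    batch_callback: Optional[Callable[[NetworkModel, ForwardCache], None]] = None,
    rates: Optional[IntrinsicLearningRates] = None,
) -> TrainingRecord:
    """Run the full batch loop: shuffle, feedforward, intrinsic update,
    weight update; per epoch record the mean training loss (and held-out
    loss when given).

    A non-finite loss halts the run and marks the record as diverged rather
    than raising. ``batch_callback(model, cache)`` is invoked after every
    forward pass (used by the gradient probe).
    """
    if len(dataset) == 0:
        raise ValueError("dataset is empty")
    if rates is None:
        rates = IntrinsicLearningRates(eta=config.intrinsic_eta)
    optimizer = AdamOptimizer(model, lr=config.synaptic_lr)
    rng = np.random.default_rng(config.seed)
    record = TrainingRecord()
    n = len(dataset)
    for _epoch in range(config.epochs):
        perm = rng.permutation(n)
        batch_losses = []
        try:
            for start in range(0, n, config.batch_size):
                idx = perm[start : start + config.batch_size]
                batch = TrainingBatch(inputs=dataset.inputs[idx], targets=dataset.targets[idx])
                cache = forward_pass(model, batch)
                if batch_callback is not None:
                    batch_callback(model, cache)
                intrinsic_step(model, cache, rates)
                _, loss = weight_step(model, cache, batch, config, optimizer)
                batch_losses.append(loss)
        except FloatingPointError:
            record.diverged = True
            break
        record.train_loss.append(float(np.mean(batch_losses)))
        if val_dataset is not None:
            try:
                record.val_loss.append(evaluate_loss(model, val_dataset))
            except FloatingPointError:
                record.diverged = True
                break
    return record


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

_STATE_FIELDS = {
    "ip": ("a", "b", IPState),
    "infomax": ("alpha", "beta", InfomaxState),
    "bn_incremental": ("a_bn", "b_bn", IncrementalBNState),
}


def save_checkpoint(model: NetworkModel, path: str | Path, metadata: Optional[dict] = None) -> None:
    """Write the model to an HDF5 file: one group per layer with W, B_add and
    the rule-state vectors; rule kind and sizes as root attributes."""
    with h5py.File(path, "w") as fh:
        fh.attrs["rule_kind"] = model.rule_kind
        fh.attrs["layer_sizes"] = np.asarray(model.layer_sizes)
        for key, val in (metadata or {}).items():
            fh.attrs[f"meta_{key}"] = val
        for l, layer in enumerate(model.layers):
            grp = fh.create_group(f"layer_{l}")
            grp.create_dataset("W", data=layer.W)
            grp.create_dataset("B_add", data=layer.B_add)
            if layer.rule_state is not None:
                f1, f2, _cls = _STATE_FIELDS[model.rule_kind]
                grp.create_dataset(f1, data=np.atleast_1d(getattr(layer.rule_state, f1)))
                grp.create_dataset(f2, data=np.atleast_1d(getattr(layer.rule_state, f2)))


def load_checkpoint(path: str | Path) -> NetworkModel:
    """Bit-exact inverse of :func:`save_checkpoint`."""
    with h5py.File(path, "r") as fh:
        rule_kind = str(fh.attrs["rule_kind"])
        sizes = [int(s) for s in fh.attrs["layer_sizes"]]
        layers = []
        for l in range(len(sizes) - 1):
            grp = fh[f"layer_{l}"]
            state: Optional[RuleState] = None
            if rule_kind != "standard":
                f1, f2, cls = _STATE_FIELDS[rule_kind]
                state = cls(**{f1: grp[f1][...], f2: grp[f2][...]})
            layers.append(LayerParams(W=grp["W"][...], B_add=grp["B_add"][...], rule_state=state))
    return NetworkModel(layers=layers, layer_sizes=sizes, rule_kind=rule_kind)  # type: ignore[arg-type]
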