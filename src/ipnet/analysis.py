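"""Verification instruments for the intrinsic rules.

* A plug-in histogram estimator of the differential entropy of a tanh
  neuron's output (support (-1, 1), ceiling ln 2 nats at the uniform).
* Fixed-distribution convergence runs: repeatedly transform one frozen batch
  with a rule, update, and trace the output entropy — the information-
  potential experiment.
* A numerical equilibrium oracle for the IP fixed point
  ``E[tanh((x-b)/a)] = 0``, ``a = 2 E[x tanh((x-b)/a)]`` on an empirical
  sample, independent of the incremental dynamics it is used to check.
  Its ``b*`` is approximately the input median: the tanh centring result.
* A gradient probe that records the mean activation derivative ``1 - y^2``
  at a chosen layer while a network trains — the vanishing-gradient
  instrument.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .data import DistributionSpec, TrainingBatch, sample_distribution
from .network import ForwardCache, NetworkModel, TrainConfig, train
from .rules import (
    IPState,
    IncrementalBNState,
    InfomaxState,
    IntrinsicLearningRates,
    RuleState,
    activation_gradient,
    bn_transform,
    bn_update,
    compute_batch_stats,
    infomax_transform,
    infomax_update,
    ip_transform,
    ip_update,
)

__all__ = [
    "DistributionSpec",
    "EntropyTrace",
    "GradientTrace",
    "histogram_entropy",
    "run_fixed_distribution",
    "iterate_ip_to_equilibrium",
    "equilibrium_oracle",
    "probe_gradients",
]

_RULES = {
    "ip": (IPState, ip_transform),
    "infomax": (InfomaxState, infomax_transform),
    "bn_incremental": (IncrementalBNState, bn_transform),
}


@dataclass
class EntropyTrace:
    """Per-iteration differential-entropy estimates of one rule's output."""

    rule: str
    entropy_nats: np.ndarray
    final_state: RuleState
    n_bins: int
    diverged: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rule": self.rule,
                "iteration": np.arange(len(self.entropy_nats)),
                "entropy_nats": self.entropy_nats,
            }
        )


@dataclass
class GradientTrace:
    """Mean activation derivative at one probed layer, per training batch."""

    layer_index: int
    grad_mean: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "layer_index": self.layer_index,
                "iteration": np.arange(len(self.grad_mean)),
                "grad_mean": self.grad_mean,
            }
        )


def histogram_entropy(y_samples: np.ndarray, n_bins: int = 100) -> float:
    """Plug-in differential entropy of samples on [-1, 1], in nats.

    Equal-width bins over the fixed support; with bin masses ``p_i`` and
    width ``delta = 2/n_bins``, ``H = -sum p_i ln p_i + ln delta`` (empty
    bins contribute nothing). Bounded above by ln 2, attained for the
    uniform distribution.
    """
    y = np.asarray(y_samples, dtype=float)
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if y.size == 0:
        raise ValueError("empty sample")
    if np.any(np.abs(y) > 1.0) or not np.all(np.isfinite(y)):
        raise ValueError("samples must lie in [-1, 1]")
    counts, _ = np.histogram(y, bins=n_bins, range=(-1.0, 1.0))
    p = counts[counts > 0] / y.size
    return float(-(p * np.log(p)).sum() + np.log(2.0 / n_bins))


def run_fixed_distribution(
    rule: str,
    dist: DistributionSpec,
    eta: float,
    iterations: int,
    n_bins: int = 100,
    half_rate_bias: bool = False,
) -> EntropyTrace:
    """Apply one rule repeatedly to a single frozen batch and trace entropy.

    The batch is drawn once from ``dist``; each iteration transforms it with
    the current state, records the output entropy, then updates the state
    from that batch's statistics. A final entropy is appended after the last
    update, so the trace has ``iterations + 1`` entries. By default the bias
    uses the full rate ``eta`` (all rules share one intrinsic rate here);
    set ``half_rate_bias`` for the network training convention.
    """
    if rule not in _RULES:
        raise ValueError(f"rule must be one of {tuple(_RULES)}")
    cls, transform = _RULES[rule]
    x = sample_distribution(dist)
    state = cls.initial()
    rates = IntrinsicLearningRates(eta=eta, eta_b=None if half_rate_bias else eta)
    entropies = []
    diverged = False
    for _ in range(iterations):
        y = transform(x, state)
        entropies.append(histogram_entropy(y, n_bins))
        stats = compute_batch_stats(x, y)
        try:
            if rule == "ip":
                state = ip_update(state, stats, rates)
            elif rule == "infomax":
                state = infomax_update(state, stats, eta)
            else:
                state = bn_update(state, stats, eta)
        except ValueError:  # non-finite state: divergence
            diverged = True
            break
    if not diverged:
        entropies.append(histogram_entropy(transform(x, state), n_bins))
    return EntropyTrace(
        rule=rule,
        entropy_nats=np.asarray(entropies),
        final_state=state,
        n_bins=n_bins,
        diverged=diverged,
    )


def iterate_ip_to_equilibrium(
    x: np.ndarray,
    eta: float = 0.05,
    max_iter: int = 20000,
    atol: float = 1e-10,
    state: Optional[IPState] = None,
) -> IPState:
    """Run the incremental IP dynamics on a frozen sample until the update
    stalls (max |change| < atol on a and b) or ``max_iter`` is reached.

    The bias uses the full rate (single-neuron convention).
    """
    x = np.asarray(x, dtype=float)
    rates = IntrinsicLearningRates(eta=eta, eta_b=eta)
    if state is None:
        state = IPState.initial()
    for _ in range(max_iter):
        y = ip_transform(x, state)
        new = ip_update(state, compute_batch_stats(x, y), rates)
        if max(abs(float(new.a - state.a)), abs(float(new.b - state.b))) < atol:
            return new
        state = new
    return state


def equilibrium_oracle(
    x: np.ndarray,
    a_init: float = 1.0,
    b_tol: float = 1e-6,
    a_rtol: float = 1e-8,
    max_iter: int = 500,
) -> tuple[float, float]:
    """Solve the coupled IP fixed point on an empirical sample.

    Nested root-finding: for the current ``a``, the bias root
    ``E[tanh((x - b)/a)] = 0`` is bracketed on [min x, max x] and solved to
    |E[y]| below ``b_tol``; then ``a`` is replaced by ``2 E[x y]`` and the
    pair is iterated to relative convergence. Independent of the incremental
    dynamics, so it serves as their oracle.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2 or np.std(x) == 0:
        raise ValueError("degenerate sample: no spread")
    lo, hi = float(x.min()), float(x.max())

    def solve_b(a: float) -> float:
        def mean_y(b: float) -> float:
            return float(np.mean(np.tanh((x - b) / a)))

        # mean_y is strictly decreasing in b; endpoints bracket the root
        if mean_y(lo) <= 0 or mean_y(hi) >= 0:
            raise ValueError("no sign change for the bias root within the sample range")
        return float(brentq(mean_y, lo, hi, xtol=1e-12))

    a = float(a_init)
    b = solve_b(a)
    for _ in range(max_iter):
        y = np.tanh((x - b) / a)
        a_new = 2.0 * float(np.mean(x * y))
        if a_new <= 0:
            raise ValueError("gain fixed point collapsed to a non-positive value")
        b_new = solve_b(a_new)
        if abs(a_new - a) <= a_rtol * abs(a):
            a, b = a_new, b_new
            break
        a, b = a_new, b_new
    if abs(float(np.mean(np.tanh((x - b) / a)))) > b_tol:
        raise RuntimeError("bias root did not reach tolerance")
    return a, b


def probe_gradients(
    model: NetworkModel,
    dataset: TrainingBatch,
    config: TrainConfig,
    layer_index: int,
) -> GradientTrace:
    """Train ``model`` on ``dataset`` recording, after each forward pass, the
    mean of ``1 - y^2`` over batch and neurons at the probed (non-output)
    layer."""
    if not (0 <= layer_index < len(model.layers)):
        raise ValueError(
            f"layer_index must name a non-output layer in [0, {len(model.layers)})"
        )
    values: list[float] = []

    def hook(_model: NetworkModel, cache: ForwardCache) -> None:
        values.append(float(np.mean(activation_gradient(cache.y[layer_index]))))

    train(model, dataset, config, batch_callback=hook)
    return GradientTrace(layer_index=layer_index, grad_mean=np.asarray(values))
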