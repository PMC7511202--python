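"""Per-neuron normalisation rules: intrinsic plasticity (IP), Infomax, and
incremental batch normalisation.

All three rules adapt an affine transform applied to a tanh neuron's input so
that the neuron's output distribution approaches the entropy-maximising
uniform distribution on (-1, 1):

* **IP** parameterises the transform as ``u = (x - b) / a`` and nudges the
  gain ``a`` toward ``2 E[xy]`` and the bias ``b`` toward the median of the
  input distribution, using only batch statistics of the neuron's own input
  ``x`` and output ``y = tanh(u)``.
* **Infomax** (Bell & Sejnowski) uses ``u = alpha * x + beta`` with the
  gradient-ascent updates on output entropy.
* **Incremental BN** learns persistent estimates of the batch mean and
  spread with the same leaky-integrator form as the IP gain, so that the
  transform converges to conventional batch standardisation without looking
  ahead at the current batch.

Everything here is stateless math on small dataclasses; per-neuron values
are numpy arrays (scalars are fine) so a whole layer updates in one call.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Union

import numpy as np

__all__ = [
    "A_FLOOR",
    "IPState",
    "InfomaxState",
    "IncrementalBNState",
    "NeuronBatchStats",
    "IntrinsicLearningRates",
    "RuleState",
    "ip_transform",
    "infomax_transform",
    "bn_transform",
    "compute_batch_stats",
    "ip_update",
    "infomax_update",
    "bn_update",
    "activation_gradient",
]

logger = logging.getLogger(__name__)

#: Lower guard on |gain| for every rule. Keeps 1/a and 1/alpha finite when a
#: neuron sees (near-)constant input; far below any gain the dynamics visit
#: on non-degenerate data, so it does not perturb them.
A_FLOOR = 1e-4

ArrayLike = Union[float, np.ndarray]


def _as_float_array(x: ArrayLike, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must be finite, got {arr!r}")
    return arr


@dataclass
class IPState:
    """Gain ``a`` (> 0) and bias ``b`` of the IP transform ``u = (x-b)/a``."""

    a: np.ndarray
    b: np.ndarray

    def __post_init__(self) -> None:
        self.a = _as_float_array(self.a, "a")
        self.b = _as_float_array(self.b, "b")
        if np.any(self.a < A_FLOOR):
            raise ValueError(f"gain a must be >= {A_FLOOR}")

    @classmethod
    def initial(cls, n: int | None = None) -> "IPState":
        """Fresh state: a = 1, b = 0 (per neuron if ``n`` is given)."""
        if n is None:
            return cls(a=np.float64(1.0), b=np.float64(0.0))
        return cls(a=np.ones(n), b=np.zeros(n))


@dataclass
class InfomaxState:
    """Gain ``alpha`` (nonzero) and bias ``beta`` of ``u = alpha*x + beta``."""

    alpha: np.ndarray
    beta: np.ndarray

    def __post_init__(self) -> None:
        self.alpha = _as_float_array(self.alpha, "alpha")
        self.beta = _as_float_array(self.beta, "beta")
        if np.any(np.abs(self.alpha) < A_FLOOR):
            raise ValueError(f"|alpha| must be >= {A_FLOOR}")

    @classmethod
    def initial(cls, n: int | None = None) -> "InfomaxState":
        if n is None:
            return cls(alpha=np.float64(1.0), beta=np.float64(0.0))
        return cls(alpha=np.ones(n), beta=np.zeros(n))


@dataclass
class IncrementalBNState:
    """Persistent scale/location estimates of incremental batch normalisation.

    ``a_bn`` tracks the population standard deviation of the input and
    ``b_bn`` its mean, each as a leaky integrator with rate ``eta``; the
    forward transform is ``tanh((x - b_bn) / a_bn)``, identical in form to IP.
    """

    a_bn: np.ndarray
    b_bn: np.ndarray

    def __post_init__(self) -> None:
        self.a_bn = _as_float_array(self.a_bn, "a_bn")
        self.b_bn = _as_float_array(self.b_bn, "b_bn")
        if np.any(self.a_bn < A_FLOOR):
            raise ValueError(f"a_bn must be >= {A_FLOOR}")

    @classmethod
    def initial(cls, n: int | None = None) -> "IncrementalBNState":
        if n is None:
            return cls(a_bn=np.float64(1.0), b_bn=np.float64(0.0))
        return cls(a_bn=np.ones(n), b_bn=np.zeros(n))


RuleState = Union[IPState, InfomaxState, IncrementalBNState]


@dataclass
class NeuronBatchStats:
    """Per-neuron moments over the current batch feeding all update rules.

    ``e_xy``, ``e_y``, ``e_x`` are arithmetic means; ``spread_x`` is the
    population (divide-by-n) standard deviation of the input.
    """

    e_xy: np.ndarray
    e_y: np.ndarray
    e_x: np.ndarray
    spread_x: np.ndarray


@dataclass
class IntrinsicLearningRates:
    """Step sizes of the intrinsic updates.

    ``eta`` drives the gain; ``eta_b`` drives the bias and defaults to
    ``eta / 2`` (the bias rate is conventionally half the gain rate).
    ``eta = 0`` is allowed and freezes the rule.
    """

    eta: float
    eta_b: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.eta < 1.0):
            raise ValueError("eta must lie in [0, 1)")
        if self.eta_b is None:
            self.eta_b = self.eta / 2.0
        if not (0.0 <= self.eta_b < 1.0):
            raise ValueError("eta_b must lie in [0, 1)")


# ---------------------------------------------------------------------------
# forward transforms
# ---------------------------------------------------------------------------

def ip_transform(x: ArrayLike, state: IPState, return_u: bool = False):
    """``y = tanh((x - b) / a)``; optionally also the pre-activation ``u``."""
    x = _as_float_array(x, "x")
    u = (x - state.b) / state.a
    y = np.tanh(u)
    return (y, u) if return_u else y


def infomax_transform(x: ArrayLike, state: InfomaxState, return_u: bool = False):
    """``y = tanh(alpha * x + beta)``."""
    x = _as_float_array(x, "x")
    u = state.alpha * x + state.beta
    y = np.tanh(u)
    return (y, u) if return_u else y


def bn_transform(x: ArrayLike, state: IncrementalBNState, return_u: bool = False):
    """``y = tanh((x - b_bn) / a_bn)`` — same functional form as IP."""
    x = _as_float_array(x, "x")
    u = (x - state.b_bn) / state.a_bn
    y = np.tanh(u)
    return (y, u) if return_u else y


# ---------------------------------------------------------------------------
# batch statistics
# ---------------------------------------------------------------------------

def compute_batch_stats(x_batch: ArrayLike, y_batch: ArrayLike, axis: int = 0) -> NeuronBatchStats:
    """Moments of aligned input/output samples over the batch axis."""
    x = np.asarray(x_batch, dtype=float)
    y = np.asarray(y_batch, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"x and y batches must align, got {x.shape} vs {y.shape}")
    if x.size == 0 or x.shape[axis] == 0:
        raise ValueError("empty batch")
    return NeuronBatchStats(
        e_xy=np.mean(x * y, axis=axis),
        e_y=np.mean(y, axis=axis),
        e_x=np.mean(x, axis=axis),
        spread_x=np.std(x, axis=axis),  # population convention (ddof=0)
    )


# ---------------------------------------------------------------------------
# one-step updates
# ---------------------------------------------------------------------------

def _floor_gain(g: np.ndarray, label: str) -> np.ndarray:
    floored = np.maximum(g, A_FLOOR)
    n = int(np.sum(g < A_FLOOR))
    if n:
        logger.warning("%s floored at %.1e for %d neuron(s)", label, A_FLOOR, n)
    return floored


def ip_update(
    state: IPState,
    stats: NeuronBatchStats,
    rates: IntrinsicLearningRates,
    gain_target_factor: float = 2.0,
) -> IPState:
    """One IP step from shared pre-update batch statistics.

    ``a' = (1 - eta) a + eta * (2 E[xy])`` — a leaky integrator whose fixed
    point is the Infomax gain equilibrium ``a* = 2 E[xy]``.
    ``b' = b + eta_b * 4 E[xy] E[y]`` — drives ``E[y]`` to zero, i.e. the
    transform's centre toward the input median.

    ``gain_target_factor`` exposes the variant ``a* = E[xy]`` (factor 1) for
    sensitivity checks; the default 2 is the rule proper.
    """
    a_new = (1.0 - rates.eta) * state.a + rates.eta * (gain_target_factor * stats.e_xy)
    b_new = state.b + rates.eta_b * (4.0 * stats.e_xy * stats.e_y)
    return IPState(a=_floor_gain(np.asarray(a_new, dtype=float), "a"), b=b_new)


def infomax_update(state: InfomaxState, stats: NeuronBatchStats, eta: float) -> InfomaxState:
    """Bell–Sejnowski entropy-gradient step:
    ``alpha' = alpha + eta (1/alpha - 2 E[xy])``, ``beta' = beta - 2 eta E[y]``.
    """
    alpha_new = state.alpha + eta * (1.0 / state.alpha - 2.0 * stats.e_xy)
    beta_new = state.beta + eta * (-2.0 * stats.e_y)
    alpha_new = np.asarray(alpha_new, dtype=float)
    # floor magnitude, preserving sign, so 1/alpha stays finite
    sign = np.where(alpha_new >= 0, 1.0, -1.0)
    floored = sign * _floor_gain(np.abs(alpha_new), "|alpha|")
    return InfomaxState(alpha=floored, beta=beta_new)


def bn_update(state: IncrementalBNState, stats: NeuronBatchStats, eta: float) -> IncrementalBNState:
    """Leaky-integrator tracking of the input mean and spread:
    ``a_bn' = (1 - eta) a_bn + eta * std(x)``,
    ``b_bn' = (1 - eta) b_bn + eta * E[x]``.
    """
    a_new = (1.0 - eta) * state.a_bn + eta * stats.spread_x
    b_new = (1.0 - eta) * state.b_bn + eta * stats.e_x
    return IncrementalBNState(a_bn=_floor_gain(np.asarray(a_new, dtype=float), "a_bn"), b_bn=b_new)


def activation_gradient(y: ArrayLike) -> np.ndarray:
    """Derivative of tanh expressed through its output: ``dy/du = 1 - y**2``.

    Only genuine tanh outputs are accepted (|y| < 1).
    """
    y = _as_float_array(y, "y")
    if np.any(np.abs(y) >= 1.0):
        raise ValueError("|y| >= 1 is not a tanh output")
    return 1.0 - y * y
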