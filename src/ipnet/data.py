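"""Seeded input generators and dataset readers.

Scalar distributions feed the single-neuron entropy/equilibrium experiments;
Gaussian-blob classification tasks stand in for image benchmarks so the
network trainer is testable without any downloads. Readers for the MNIST IDX
and CIFAR-10 binary-batch formats are provided for running the full-scale
experiments on locally available copies, together with fixture writers used
by the test suite.
"""

from __future__ import annotations

import math
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np

__all__ = [
    "DistributionSpec",
    "TrainingBatch",
    "BlobTaskSpec",
    "sample_distribution",
    "make_blob_task",
    "read_mnist_idx",
    "write_mnist_idx",
    "read_cifar10",
    "write_cifar10_batch",
]

_FAMILIES = ("uniform", "gaussian", "exponential", "custom-sample")


@dataclass
class DistributionSpec:
    """A parametric scalar input distribution with a fixed seed.

    params by family — uniform: ``width``, ``center``; gaussian: ``mu``,
    ``sigma``; exponential: ``rate``; custom-sample: ``values`` (drawn from
    with replacement). ``median`` is the analytic median when known.
    """

    family: str
    params: dict
    n: int
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; one of {_FAMILIES}")
        if self.n < 1:
            raise ValueError("n must be >= 1")
        p = self.params
        if self.family == "uniform":
            if p.get("width", 0.0) <= 0:
                raise ValueError("uniform width must be > 0")
        elif self.family == "gaussian":
            if p.get("sigma", 0.0) <= 0:
                raise ValueError("gaussian sigma must be > 0")
        elif self.family == "exponential":
            if p.get("rate", 0.0) <= 0:
                raise ValueError("exponential rate must be > 0")
        elif self.family == "custom-sample":
            if len(np.atleast_1d(p.get("values", []))) == 0:
                raise ValueError("custom-sample needs non-empty values")

    @property
    def median(self) -> float:
        """Analytic median of the family (empirical for custom samples)."""
        p = self.params
        if self.family == "uniform":
            return float(p["center"])
        if self.family == "gaussian":
            return float(p["mu"])
        if self.family == "exponential":
            return math.log(2.0) / float(p["rate"])
        return float(np.median(np.asarray(p["values"], dtype=float)))


def sample_distribution(spec: DistributionSpec) -> np.ndarray:
    """Reproducible draw of ``spec.n`` scalars from the specified family."""
    rng = np.random.default_rng(spec.seed)
    p = spec.params
    if spec.family == "uniform":
        half = p["width"] / 2.0
        return rng.uniform(p["center"] - half, p["center"] + half, size=spec.n)
    if spec.family == "gaussian":
        return rng.normal(p["mu"], p["sigma"], size=spec.n)
    if spec.family == "exponential":
        return rng.exponential(1.0 / p["rate"], size=spec.n)
    values = np.asarray(p["values"], dtype=float)
    return rng.choice(values, size=spec.n, replace=True)


@dataclass
class TrainingBatch:
    """Flat feature vectors with integer class labels."""

    inputs: np.ndarray  # (n_samples, n_features)
    targets: np.ndarray  # (n_samples,), values in [0, n_classes)

    def __post_init__(self) -> None:
        self.inputs = np.asarray(self.inputs, dtype=float)
        self.targets = np.asarray(self.targets, dtype=int)
        if self.inputs.ndim != 2:
            raise ValueError("inputs must be 2-D (samples, features)")
        if self.targets.shape != (self.inputs.shape[0],):
            raise ValueError("one target per input row required")
        if self.inputs.shape[0] and self.targets.min() < 0:
            raise ValueError("negative class label")

    def __len__(self) -> int:
        return self.inputs.shape[0]


@dataclass
class BlobTaskSpec:
    """Gaussian-blob classification task.

    Class centres are drawn once from N(centre_loc, centre_scale^2) per
    dimension; samples add isotropic noise of scale ``noise_sigma``. The
    defaults give a 10-class, 20-dimensional task whose inputs are
    deliberately *uncentered* (centre_loc = 1), mimicking the positive,
    off-centre pixel intensities of image benchmarks that make saturating
    tanh stacks hard for a standard network.
    """

    n_classes: int = 10
    dims: int = 20
    n_per_class: int = 200
    noise_sigma: float = 1.0
    centre_loc: float = 1.0
    centre_scale: float = 2.0
    seed: int = 0
    n_test_per_class: int = 50

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if self.dims < 1:
            raise ValueError("dims must be >= 1")
        if self.noise_sigma <= 0:
            raise ValueError("noise_sigma must be > 0")
        if self.n_per_class < 1:
            raise ValueError("empty dataset: n_per_class must be >= 1")


def make_blob_task(spec: BlobTaskSpec) -> tuple[TrainingBatch, TrainingBatch]:
    """Seeded labelled blob dataset as a (train, test) pair.

    Label balance is exact by construction; rows are shuffled so batches are
    class-mixed.
    """
    rng = np.random.default_rng(spec.seed)
    centres = rng.normal(spec.centre_loc, spec.centre_scale, size=(spec.n_classes, spec.dims))

    def draw(n_per_class: int) -> TrainingBatch:
        xs, ts = [], []
        for c in range(spec.n_classes):
            xs.append(centres[c] + rng.normal(0.0, spec.noise_sigma, size=(n_per_class, spec.dims)))
            ts.append(np.full(n_per_class, c))
        inputs = np.concatenate(xs)
        targets = np.concatenate(ts)
        perm = rng.permutation(len(targets))
        return TrainingBatch(inputs=inputs[perm], targets=targets[perm])

    return draw(spec.n_per_class), draw(max(1, spec.n_test_per_class))


# ---------------------------------------------------------------------------
# MNIST IDX format
# ---------------------------------------------------------------------------

_IDX_IMAGES_MAGIC = 2051
_IDX_LABELS_MAGIC = 2049


def read_mnist_idx(images_path: str | Path, labels_path: str | Path, scale: bool = True) -> TrainingBatch:
    """Read an IDX image/label file pair into flat [0,1] feature vectors."""
    images_path, labels_path = Path(images_path), Path(labels_path)
    raw = images_path.read_bytes()
    if len(raw) < 16:
        raise ValueError(f"{images_path}: truncated IDX image file")
    magic, n, rows, cols = struct.unpack(">iiii", raw[:16])
    if magic != _IDX_IMAGES_MAGIC:
        raise ValueError(f"{images_path}: bad IDX image magic {magic}")
    if len(raw) != 16 + n * rows * cols:
        raise ValueError(f"{images_path}: size does not match header")
    images = np.frombuffer(raw, dtype=np.uint8, offset=16).reshape(n, rows * cols)

    raw = labels_path.read_bytes()
    if len(raw) < 8:
        raise ValueError(f"{labels_path}: truncated IDX label file")
    magic, n_labels = struct.unpack(">ii", raw[:8])
    if magic != _IDX_LABELS_MAGIC:
        raise ValueError(f"{labels_path}: bad IDX label magic {magic}")
    if len(raw) != 8 + n_labels:
        raise ValueError(f"{labels_path}: size does not match header")
    if n_labels != n:
        raise ValueError(f"image count {n} != label count {n_labels}")
    labels = np.frombuffer(raw, dtype=np.uint8, offset=8)

    inputs = images.astype(float)
    if scale:
        inputs = inputs / 255.0
    return TrainingBatch(inputs=inputs, targets=labels.astype(int))


def write_mnist_idx(
    images: np.ndarray, labels: np.ndarray, images_path: str | Path, labels_path: str | Path
) -> None:
    """Write uint8 images of shape (n, rows, cols) and labels as IDX files."""
    images = np.asarray(images, dtype=np.uint8)
    labels = np.asarray(labels, dtype=np.uint8)
    n, rows, cols = images.shape
    with open(images_path, "wb") as fh:
        fh.write(struct.pack(">iiii", _IDX_IMAGES_MAGIC, n, rows, cols))
        fh.write(images.tobytes())
    with open(labels_path, "wb") as fh:
        fh.write(struct.pack(">ii", _IDX_LABELS_MAGIC, n))
        fh.write(labels.tobytes())


# ---------------------------------------------------------------------------
# CIFAR-10 binary batches
# ---------------------------------------------------------------------------

_CIFAR_RECORD = 3073  # 1 label byte + 3*32*32 pixel bytes


def read_cifar10(batch_dir: str | Path, pattern: str = "*.bin", scale: bool = True) -> TrainingBatch:
    """Read all CIFAR-10 binary batch files under ``batch_dir``."""
    batch_dir = Path(batch_dir)
    files = sorted(batch_dir.glob(pattern))
    if not files:
        raise ValueError(f"no CIFAR-10 batch files matching {pattern!r} in {batch_dir}")
    inputs, targets = [], []
    for path in files:
        raw = path.read_bytes()
        if len(raw) == 0 or len(raw) % _CIFAR_RECORD != 0:
            raise ValueError(f"{path}: length {len(raw)} is not a multiple of {_CIFAR_RECORD}")
        records = np.frombuffer(raw, dtype=np.uint8).reshape(-1, _CIFAR_RECORD)
        targets.append(records[:, 0].astype(int))
        inputs.append(records[:, 1:].astype(float))
    x = np.concatenate(inputs)
    if scale:
        x = x / 255.0
    return TrainingBatch(inputs=x, targets=np.concatenate(targets))


def write_cifar10_batch(pixels: np.ndarray, labels: np.ndarray, path: str | Path) -> None:
    """Write uint8 pixel rows of shape (n, 3072) with labels as one batch file."""
    pixels = np.asarray(pixels, dtype=np.uint8)
    labels = np.asarray(labels, dtype=np.uint8)
    if pixels.ndim != 2 or pixels.shape[1] != _CIFAR_RECORD - 1:
        raise ValueError("pixels must have shape (n, 3072)")
    records = np.concatenate([labels[:, None], pixels], axis=1)
    Path(path).write_bytes(records.astype(np.uint8).tobytes())
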