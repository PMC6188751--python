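"""Bag/instance data model, kernels and the quantile operator.

Multiple instance learning (MIL) attaches labels to *bags* (here: the set of
3D texture patches sampled from one subject's CT scan) rather than to
individual instances.  The classical witness assumption says a bag is
positive iff at least one instance is positive, i.e. the bag label is the
``max`` over instance labels.  The quantile relaxation replaces ``max`` by an
upper nearest-rank quantile so that a handful of lesion-like patches cannot
flip a healthy subject's label.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "Instance",
    "Bag",
    "KernelSpec",
    "MILParams",
    "kernel",
    "kernel_matrix",
    "quantile_agg",
    "bags_to_arrays",
]


@dataclass(frozen=True)
class Instance:
    """A single patch: its feature vector plus provenance."""

    features: np.ndarray
    subject_id: str
    patch_center: tuple[int, int, int] | None = None

    def __post_init__(self) -> None:
        feats = np.asarray(self.features, dtype=float)
        if not np.all(np.isfinite(feats)):
            raise ValueError("instance features must be finite")
        object.__setattr__(self, "features", feats)


@dataclass
class Bag:
    """A subject's set of instances with a weak (subject-level) label.

    ``label`` is +1 (diseased), -1 (healthy) or ``None`` (unknown, e.g. at
    test time).  ``label_channel`` records which covariate threshold produced
    the label: COPD diagnosis (GOLD A-D) or DLCO < 60 % predicted.
    """

    instances: list[Instance]
    label: int | None = None
    label_channel: Literal["copd", "dlco"] | None = None

    def __post_init__(self) -> None:
        if len(self.instances) < 1:
            raise ValueError("a bag needs at least one instance")
        sids = {inst.subject_id for inst in self.instances}
        if len(sids) != 1:
            raise ValueError("all instances in a bag must share subject_id")
        if self.label is not None and self.label not in (-1, 1):
            raise ValueError("bag label must be +1, -1 or None")

    @property
    def subject_id(self) -> str:
        return self.instances[0].subject_id

    @property
    def X(self) -> np.ndarray:
        """(n_i, d) feature matrix of the bag's instances."""
        return np.vstack([inst.features for inst in self.instances])

    def __len__(self) -> int:
        return len(self.instances)


@dataclass(frozen=True)
class KernelSpec:
    """Instance-level similarity: inhomogeneous polynomial or Gaussian RBF.

    ``bandwidth`` is interpreted on z-scored features (the classifiers
    standardize features with training-fold statistics before any kernel
    evaluation), which is the only scale on which the customary bandwidth
    grid {8..20} is meaningful for features spanning orders of magnitude.
    """

    family: Literal["polynomial", "rbf"]
    degree: int = 1
    bandwidth: float = 10.0

    def __post_init__(self) -> None:
        if self.family == "polynomial":
            if self.degree not in (1, 2):
                raise ValueError("polynomial degree must be 1 or 2")
        elif self.family == "rbf":
            if not self.bandwidth > 0:
                raise ValueError("rbf bandwidth must be > 0")
        else:
            raise ValueError(f"unknown kernel family {self.family!r}")


@dataclass(frozen=True)
class MILParams:
    """Hyper-parameters shared by the two MIL classifiers."""

    kernel: KernelSpec = field(default_factory=lambda: KernelSpec("rbf", bandwidth=10.0))
    C: float = 1.0
    q: float = 1.0

    def __post_init__(self) -> None:
        if not self.C > 0:
            raise ValueError("C must be > 0")
        if not 0.0 < self.q <= 1.0:
            raise ValueError("quantile q must lie in (0, 1]")


def kernel(x: np.ndarray, z: np.ndarray, spec: KernelSpec) -> float:
    """Evaluate k(x, z) for a single pair of instance vectors."""
    x = np.asarray(x, dtype=float)
    z = np.asarray(z, dtype=float)
    if x.shape != z.shape:
        raise ValueError(f"dimension mismatch: {x.shape} vs {z.shape}")
    if spec.family == "polynomial":
        return float((x @ z + 1.0) ** spec.degree)
    d2 = float(np.sum((x - z) ** 2))
    return math.exp(-d2 / (2.0 * spec.bandwidth**2))


def kernel_matrix(X: np.ndarray, Z: np.ndarray, spec: KernelSpec) -> np.ndarray:
    """Pairwise kernel matrix K[i, j] = k(X[i], Z[j])."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    if X.shape[1] != Z.shape[1]:
        raise ValueError("dimension mismatch between instance sets")
    if spec.family == "polynomial":
        return (X @ Z.T + 1.0) ** spec.degree
    # squared euclidean distances via the expansion trick
    d2 = (
        np.sum(X**2, axis=1)[:, None]
        + np.sum(Z**2, axis=1)[None, :]
        - 2.0 * (X @ Z.T)
    )
    np.maximum(d2, 0.0, out=d2)
    return np.exp(-d2 / (2.0 * spec.bandwidth**2))


def quantile_agg(values: Sequence[float] | np.ndarray, q: float) -> float:
    """Upper nearest-rank quantile of ``values``.

    Returns the k-th largest value with ``k = ceil((1 - q) * n)`` clamped to
    ``[1, n]``; ``q = 1`` therefore returns the maximum (the classical MIL
    witness rule).  Applied to +/-1 labels, ``quantile_agg(labels, q) == +1``
    holds exactly when at least ``k`` labels are positive — for q = 0.5, half
    of the instances must be positive for the bag to be positive.

    No interpolation is used: the operator acts on hard +/-1 labels during
    training, where interpolated values would be meaningless.
    """
    vals = np.asarray(values, dtype=float).ravel()
    n = vals.size
    if n == 0:
        raise ValueError("quantile_agg of an empty collection")
    if not 0.0 < q <= 1.0:
        raise ValueError("q must lie in (0, 1]")
    k = math.ceil((1.0 - q) * n)
    k = min(max(k, 1), n)
    # k-th largest == element at index n-k of the ascending sort
    return float(np.partition(vals, n - k)[n - k])


def min_positive_instances(n: int, q: float) -> int:
    """Number of positive instance labels needed for a positive bag.

    ``quantile_agg(labels, q) == +1`` iff at least this many of the ``n``
    labels are +1.  Lower q is stricter: q = 0.25 demands 75 % positives.
    """
    if n < 1:
        raise ValueError("bag size must be >= 1")
    return min(max(math.ceil((1.0 - q) * n), 1), n)


def bags_to_arrays(bags: Sequence[Bag]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack bags into (X, bag_index, y) arrays for vectorised training."""
    X = np.vstack([bag.X for bag in bags])
    idx = np.concatenate([np.full(len(b), i, dtype=int) for i, b in enumerate(bags)])
    y = np.array([0 if b.label is None else b.label for b in bags], dtype=int)
    return X, idx, y
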