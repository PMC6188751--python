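"""miSVM-Q: instance-level MIL SVM with a quantile-relaxed bag constraint.

The classical miSVM searches for an instance classifier that separates
instances as well as possible while keeping each bag's label equal to the
max over its (unknown) instance labels.  The quantile relaxation replaces
max by an upper nearest-rank quantile, so a positive bag must contain at
least ``ceil((1 - q) * n_i)`` positive instances and a few lesion-like
patches can no longer flip a healthy bag.

Optimization follows the standard iterative label-imputation heuristic:
instance labels start at their bag labels; a kernel SVM is trained on the
imputed labels; labels are re-imputed from the decision values subject to
the bag constraints; repeat until the imputation is stable (max 20 rounds).
Decision values are mapped to [0, 1] posteriors with a Platt-style sigmoid
fitted on the final training decision values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.svm import SVC

from .mil import Bag, MILParams, bags_to_arrays, kernel_matrix, min_positive_instances, quantile_agg

__all__ = ["MisvmQModel", "fit", "predict_instances", "predict_bag"]

_MAX_ITER = 20


@dataclass
class _Standardizer:
    mean: np.ndarray
    scale: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "_Standardizer":
        mean = X.mean(axis=0)
        scale = X.std(axis=0)
        scale[scale == 0] = 1.0
        return cls(mean=mean, scale=scale)

    def __call__(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean) / self.scale


@dataclass
class _PlattMap:
    """Monotone sigmoid from decision value to posterior probability."""

    a: float  # slope, constrained >= 0 so the map is nondecreasing
    b: float

    @classmethod
    def fit(cls, decision: np.ndarray, labels: np.ndarray) -> "_PlattMap":
        dec = np.asarray(decision, dtype=float).reshape(-1, 1)
        y = (np.asarray(labels) > 0).astype(int)
        if y.min() == y.max():
            # degenerate: one class; fall back to a unit-slope sigmoid
            return cls(a=1.0, b=-float(dec.mean()))
        lr = LogisticRegression(C=1e2, solver="lbfgs")
        lr.fit(dec, y)
        a = float(lr.coef_[0, 0])
        b = float(lr.intercept_[0])
        if a < 0:  # enforce monotone nondecreasing posterior_map
            a, b = 1.0, -float(dec.mean())
        return cls(a=a, b=b)

    def __call__(self, decision: np.ndarray) -> np.ndarray:
        z = np.clip(self.a * np.asarray(decision, dtype=float) + self.b, -500, 500)
        return 1.0 / (1.0 + np.exp(-z))


@dataclass
class MisvmQModel:
    params: MILParams
    standardizer: _Standardizer
    train_X: np.ndarray  # standardized training instances (SVC support columns)
    svc: SVC
    posterior_map: _PlattMap
    converged: bool
    n_iterations: int

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        Xs = self.standardizer(np.asarray(X, dtype=float))
        if Xs.shape[1] != self.train_X.shape[1]:
            raise ValueError("feature dimension mismatch with trained model")
        K = kernel_matrix(Xs, self.train_X, self.params.kernel)
        return self.svc.decision_function(K)


def _impute_positive_bag(decision: np.ndarray, q: float) -> np.ndarray:
    """Instance labels for a positive bag given decision values.

    Sign-based labels, then the top ``m = ceil((1-q) n)`` instances by
    decision value are forced positive so the bag's quantile constraint
    holds (at minimum the single top instance).  Ties break on the stable
    instance index (argsort is stable on the negated values).
    """
    n = decision.size
    labels = np.where(decision > 0, 1, -1)
    m = min_positive_instances(n, q)
    order = np.argsort(-decision, kind="stable")
    labels[order[:m]] = 1
    return labels


def fit(bags: list[Bag], params: MILParams, max_iter: int = _MAX_ITER) -> MisvmQModel:
    """Train miSVM-Q by iterative label imputation.

    Raises on single-class input.  If the imputation does not stabilise
    within ``max_iter`` rounds the best iterate (by training bag accuracy,
    later iterations winning ties) is returned with ``converged=False``.
    """
    y_bags = np.array([b.label for b in bags])
    if any(b.label is None for b in bags):
        raise ValueError("all bags must be labeled")
    if len(np.unique(y_bags)) < 2:
        raise ValueError("both classes must be present")

    X_raw, bag_idx, _ = bags_to_arrays(bags)
    std = _Standardizer.fit(X_raw)
    X = std(X_raw)
    K = kernel_matrix(X, X, params.kernel)
    inst_bag_label = y_bags[bag_idx]

    labels = inst_bag_label.copy()
    best: tuple[float, int, SVC, np.ndarray] | None = None
    converged = False
    n_done = 0
    for it in range(max_iter):
        n_done = it + 1
        svc = SVC(C=params.C, kernel="precomputed")
        svc.fit(K, labels)
        decision = svc.decision_function(K)

        # training bag accuracy under the quantile rule, for best-iterate tracking
        bag_pred = np.array(
            [
                1 if quantile_agg(np.sign(decision[bag_idx == i]), params.q) > 0 else -1
                for i in range(len(bags))
            ]
        )
        acc = float(np.mean(bag_pred == y_bags))
        if best is None or acc >= best[0]:
            best = (acc, it, svc, decision)

        new_labels = np.where(inst_bag_label < 0, -1, labels)
        for i in np.flatnonzero(y_bags > 0):
            sel = bag_idx == i
            new_labels[sel] = _impute_positive_bag(decision[sel], params.q)
        if np.array_equal(new_labels, labels):
            converged = True
            break
        labels = new_labels

    assert best is not None
    _, _, svc, decision = best
    pmap = _PlattMap.fit(decision, labels)
    return MisvmQModel(
        params=params,
        standardizer=std,
        train_X=X,
        svc=svc,
        posterior_map=pmap,
        converged=converged,
        n_iterations=n_done,
    )


def predict_instances(model: MisvmQModel, bag: Bag) -> np.ndarray:
    """Per-instance posteriors f(x_ij) in [0, 1]."""
    return model.posterior_map(model.decision_values(bag.X))


def predict_bag(model: MisvmQModel, bag: Bag) -> float:
    """Bag posterior f(B_i) = quantile of instance posteriors at the model's q.

    The hard bag label is ``sign(f(B_i) - 0.5)`` with the default threshold
    of 0.5.
    """
    post = predict_instances(model, bag)
    return float(quantile_agg(post, model.params.q))
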