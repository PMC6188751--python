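"""MILES-Q: bag-level MIL via quantile-relaxed similarity embedding.

MILES represents each bag by its similarity to every training instance
(candidate prototype) and selects the discriminative prototypes with an
L1-regularized (1-norm) linear classifier, realized here as a linear SVM
with L1 penalty and squared hinge loss.  The classical similarity is the
max kernel value over the bag's instances; the quantile relaxation uses the
upper nearest-rank quantile instead, so a bag must contain several
prototype-like instances before it counts as similar to that prototype.

Instance scoring (the rule the embedding does not define by itself): an
instance is credited with a prototype's weighted similarity whenever it lies
in the top-k set that determines the bag's quantile aggregate for that
prototype (k = ceil((1-q) * n_i); ties at the k-th value are all credited).
The per-instance sums of credited contributions, plus the intercept, pass
through the same Platt map as bag decisions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from sklearn.svm import LinearSVC

from .mil import Bag, MILParams, kernel_matrix, quantile_agg

from .misvm import _PlattMap, _Standardizer

__all__ = ["MilesQModel", "embed", "fit", "predict_bag", "predict_instances"]


def embed(
    bag_X: np.ndarray,
    prototypes: np.ndarray,
    params: MILParams,
) -> np.ndarray:
    """Quantile similarity embedding s[m] = quantile_j k(x_ij, x_m).

    ``bag_X`` and ``prototypes`` must already live on the same (standardized)
    scale.  With q = 1 this is the classical MILES max-similarity embedding.
    """
    if bag_X.shape[0] == 0:
        raise ValueError("empty bag")
    K = kernel_matrix(bag_X, prototypes, params.kernel)  # (n_i, M)
    n = K.shape[0]
    k = min(max(math.ceil((1.0 - params.q) * n), 1), n)
    # k-th largest along axis 0
    return np.partition(K, n - k, axis=0)[n - k, :]


@dataclass
class MilesQModel:
    params: MILParams
    standardizer: _Standardizer
    prototypes: np.ndarray  # standardized retained prototypes (M', d)
    prototype_indices: np.ndarray  # into the original training instance stack
    weights: np.ndarray  # (M',) nonzero weights
    intercept: float
    posterior_map: _PlattMap

    @property
    def n_prototypes(self) -> int:
        return int(self.prototypes.shape[0])

    def bag_decision(self, bag: Bag) -> float:
        Xs = self.standardizer(bag.X)
        if self.n_prototypes == 0:
            return self.intercept
        s = embed(Xs, self.prototypes, self.params)
        return float(s @ self.weights + self.intercept)


def fit(bags: list[Bag], params: MILParams) -> MilesQModel:
    """Embed every training bag against all training instances and fit the
    sparse linear classifier; retained prototypes are the instances with
    nonzero weight."""
    y = np.array([b.label for b in bags])
    if any(b.label is None for b in bags):
        raise ValueError("all bags must be labeled")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")

    X_all = np.vstack([b.X for b in bags])
    std = _Standardizer.fit(X_all)
    Xs_all = std(X_all)
    bag_Xs = [std(b.X) for b in bags]

    S = np.vstack([embed(bx, Xs_all, params) for bx in bag_Xs])  # (N, M)
    clf = LinearSVC(
        C=params.C, penalty="l1", loss="squared_hinge", dual=False, max_iter=20000
    )
    clf.fit(S, y)
    w = clf.coef_.ravel()
    nz = np.flatnonzero(w != 0.0)
    decision = S @ w + clf.intercept_[0]
    pmap = _PlattMap.fit(decision, y)
    return MilesQModel(
        params=params,
        standardizer=std,
        prototypes=Xs_all[nz],
        prototype_indices=nz,
        weights=w[nz],
        intercept=float(clf.intercept_[0]),
        posterior_map=pmap,
    )


def predict_bag(model: MilesQModel, bag: Bag) -> float:
    """Bag posterior in [0, 1] from the sparse prototype similarity model."""
    return float(model.posterior_map(np.array([model.bag_decision(bag)]))[0])


def predict_instances(model: MilesQModel, bag: Bag) -> np.ndarray:
    """Per-instance posteriors by attained-prototype contribution (see module
    docstring)."""
    Xs = model.standardizer(bag.X)
    n = Xs.shape[0]
    if n == 0:
        raise ValueError("empty bag")
    if model.n_prototypes == 0:
        return model.posterior_map(np.full(n, model.intercept))
    K = kernel_matrix(Xs, model.prototypes, model.params.kernel)  # (n, M')
    k = min(max(math.ceil((1.0 - model.params.q) * n), 1), n)
    kth = np.partition(K, n - k, axis=0)[n - k, :]  # (M',) quantile per prototype
    credited = K >= kth[None, :] - 1e-12  # ties at the k-th value all credited
    contrib = (K * credited) @ model.weights + model.intercept
    return model.posterior_map(contrib)
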