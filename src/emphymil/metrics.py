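"""Bag- and instance-level metrics, density baseline, statistical comparisons.

Separability is the instance-level proxy metric for weakly supervised
classifiers: the difference between the average instance posterior in true
positive bags and in true negative bags,

    S = (1 / sum_{y_i=+1} n_i) sum_{y_i=+1} f(x_ij)
      - (1 / sum_{y_i=-1} n_i) sum_{y_i=-1} f(x_ij),

bounded in [-1, 1].  It rewards classifiers whose posteriors actually
separate lesion-like from healthy patches even when both classify every bag
correctly.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score

__all__ = [
    "separability",
    "bag_auc",
    "laa_percentage",
    "spearman",
    "compare_correlations_fisher",
    "dice",
]


def separability(
    positive_bag_posteriors: list[np.ndarray] | list[list[float]],
    negative_bag_posteriors: list[np.ndarray] | list[list[float]],
) -> float:
    """Separability S of instance posteriors grouped by true bag label.

    Instance counts weight the averages naturally: all instances from
    positive bags are pooled, ditto negative.
    """
    if len(positive_bag_posteriors) == 0 or len(negative_bag_posteriors) == 0:
        raise ValueError("need at least one positive and one negative bag")
    pos = np.concatenate([np.asarray(p, dtype=float).ravel() for p in positive_bag_posteriors])
    neg = np.concatenate([np.asarray(p, dtype=float).ravel() for p in negative_bag_posteriors])
    if np.any((pos < 0) | (pos > 1)) or np.any((neg < 0) | (neg > 1)):
        raise ValueError("posteriors must lie in [0, 1]")
    return float(pos.mean() - neg.mean())


def bag_auc(bag_posteriors: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve for bag posteriors vs true +/-1 bag labels.

    Mann-Whitney formulation; tied posteriors are credited 0.5.
    """
    y = np.asarray(labels)
    post = np.asarray(bag_posteriors, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present for AUC")
    return float(roc_auc_score((y > 0).astype(int), post))


def laa_percentage(
    volume: np.ndarray, lung_mask: np.ndarray, threshold: float = -950.0
) -> float:
    """Percentage of in-mask voxels strictly below ``threshold`` HU.

    The classical density-mask emphysema score (LAA%); the conventional
    threshold is -950 HU.
    """
    mask = np.asarray(lung_mask).astype(bool)
    if not mask.any():
        raise ValueError("empty lung mask")
    vals = np.asarray(volume, dtype=float)[mask]
    return float(100.0 * np.mean(vals < threshold))


def _exact_spearman_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p for small n (enumerate all pairings)."""
    n = rx.size
    denom = np.sum((rx - rx.mean()) ** 2)
    count = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        ryp = ry[list(perm)]
        rho = np.sum((rx - rx.mean()) * (ryp - ry.mean())) / math.sqrt(
            denom * np.sum((ry - ry.mean()) ** 2)
        )
        if abs(rho) >= abs(rho_obs) - 1e-12:
            count += 1
        total += 1
    return count / total


def spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rank correlation with average-rank ties; two-sided p.

    For n <= 7 the p-value is the exact permutation probability (all n!
    pairings); otherwise the large-sample t approximation is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be paired 1-D arrays")
    if x.size < 5:
        raise ValueError("need at least 5 pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in one of the variables")
    rho, p = stats.spearmanr(x, y)
    rho = float(rho)
    if x.size <= 7:
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        p = _exact_spearman_p(rx, ry, rho)
    return rho, float(p)


def compare_correlations_fisher(
    rho1: float, n1: int, rho2: float, n2: int
) -> tuple[float, float]:
    """Compare two correlations from independent samples via Fisher r-to-z.

    z = (atanh(rho1) - atanh(rho2)) / sqrt(1/(n1-3) + 1/(n2-3)), two-sided p
    from the standard normal.
    """
    if abs(rho1) >= 1 or abs(rho2) >= 1:
        raise ValueError("|rho| must be < 1")
    if n1 <= 3 or n2 <= 3:
        raise ValueError("need n > 3 in both samples")
    z = (math.atanh(rho1) - math.atanh(rho2)) / math.sqrt(
        1.0 / (n1 - 3) + 1.0 / (n2 - 3)
    )
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice similarity coefficient 2|A n B| / (|A| + |B|).

    Two empty masks agree perfectly by convention (DSC = 1).
    """
    a = np.asarray(mask_a).astype(bool)
    b = np.asarray(mask_b).astype(bool)
    if a.shape != b.shape:
        raise ValueError("mask shapes differ")
    sa, sb = int(a.sum()), int(b.sum())
    if sa + sb == 0:
        return 1.0
    return float(2.0 * np.logical_and(a, b).sum() / (sa + sb))
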