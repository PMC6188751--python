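"""3D gray-level co-occurrence (Haralick) texture features.

A gray-level co-occurrence matrix (GLCM) is the joint distribution of
quantized intensities of voxel pairs separated by a fixed offset.  In 3D the
26-neighbourhood collapses to 13 unique directions (one per non-antiparallel
offset); each is evaluated at 5 voxel distances and summarised by 12 Haralick
statistics, giving the 13 x 5 x 12 = 780-dimensional patch descriptor.

Feature ordering is frozen as direction-major: for each direction (in
``DIRECTIONS_13`` order), for each distance (ascending), the 12 statistics in
``HARALICK_NAMES`` order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DIRECTIONS_13",
    "HARALICK_NAMES",
    "GlcmConfig",
    "Glcm",
    "quantize",
    "glcm",
    "haralick",
    "cooc_features",
    "cooc_feature_names",
]

# The 13 unique 3D offsets: half of the 26 neighbours, one per +/- pair.
DIRECTIONS_13: tuple[tuple[int, int, int], ...] = (
    (1, 0, 0),
    (0, 1, 0),
    (0, 0, 1),
    (1, 1, 0),
    (1, -1, 0),
    (1, 0, 1),
    (1, 0, -1),
    (0, 1, 1),
    (0, 1, -1),
    (1, 1, 1),
    (1, 1, -1),
    (1, -1, 1),
    (1, -1, -1),
)

# Statistic order is frozen; "contrast" and "inertia" are both listed in the
# classical 12-statistic set although their defining sums coincide (both are
# sum (i-j)^2 p(i,j)); they are kept as two slots deliberately.
HARALICK_NAMES: tuple[str, ...] = (
    "energy",
    "entropy",
    "correlation",
    "contrast",
    "homogeneity",
    "variance",
    "sum_mean",
    "inverse_difference_moment",
    "inertia",
    "cluster_shade",
    "cluster_tendency",
    "max_probability",
)


@dataclass(frozen=True)
class GlcmConfig:
    """Quantization and pairing configuration.

    ``hu_window`` clamps Hounsfield units before linear binning into
    ``n_levels`` equal-width levels; 32 levels over (-1024, 0) HU keeps
    41^3-patch GLCMs well populated while resolving the parenchyma/air
    contrast that matters for emphysema.
    """

    n_levels: int = 32
    distances: tuple[int, ...] = (1, 2, 3, 4, 5)
    directions: tuple[tuple[int, int, int], ...] = DIRECTIONS_13
    symmetric: bool = True
    hu_window: tuple[float, float] = (-1024.0, 0.0)

    def __post_init__(self) -> None:
        if self.n_levels < 2:
            raise ValueError("n_levels must be >= 2")
        if any(d < 1 for d in self.distances):
            raise ValueError("distances must be strictly positive integers")
        if self.hu_window[0] >= self.hu_window[1]:
            raise ValueError("hu_window must satisfy low < high")
        seen: set[tuple[int, int, int]] = set()
        for d in self.directions:
            neg = (-d[0], -d[1], -d[2])
            if d in seen or neg in seen:
                raise ValueError(f"directions contain an antiparallel pair: {d}")
            seen.add(d)


@dataclass(frozen=True)
class Glcm:
    """A normalized co-occurrence matrix for one (direction, distance)."""

    matrix: np.ndarray
    distance: int
    direction: tuple[int, int, int]


def quantize(patch: np.ndarray, config: GlcmConfig) -> np.ndarray:
    """Clamp HU to ``config.hu_window`` and bin linearly into n_levels levels.

    Values at the upper clamp map to level ``n_levels - 1``.
    """
    patch = np.asarray(patch, dtype=float)
    if patch.size == 0:
        raise ValueError("cannot quantize an empty patch")
    low, high = config.hu_window
    clipped = np.clip(patch, low, high)
    scaled = (clipped - low) / (high - low) * config.n_levels
    levels = np.floor(scaled).astype(np.int64)
    np.clip(levels, 0, config.n_levels - 1, out=levels)
    return levels


def glcm(
    quantized: np.ndarray,
    direction: tuple[int, int, int],
    distance: int,
    n_levels: int,
    symmetric: bool = True,
) -> Glcm:
    """Co-occurrence matrix of ordered pairs (v, v + distance*direction).

    Counts every voxel pair whose both ends lie inside the grid; with
    ``symmetric`` the transpose is accumulated as well.  Normalized to sum 1.
    """
    quantized = np.asarray(quantized)
    if distance < 1:
        raise ValueError("distance must be >= 1")
    off = tuple(int(distance) * int(c) for c in direction)
    src_slices, dst_slices = [], []
    for dim, o in zip(quantized.shape, off):
        span = dim - abs(o)
        if span <= 0:
            raise ValueError(
                f"empty co-occurrence: offset {off} does not fit a grid of shape "
                f"{quantized.shape}"
            )
        if o >= 0:
            src_slices.append(slice(0, span))
            dst_slices.append(slice(o, o + span))
        else:
            src_slices.append(slice(-o, -o + span))
            dst_slices.append(slice(0, span))
    a = quantized[tuple(src_slices)].ravel()
    b = quantized[tuple(dst_slices)].ravel()
    counts = np.bincount(a * n_levels + b, minlength=n_levels * n_levels)
    mat = counts.reshape(n_levels, n_levels).astype(float)
    if symmetric:
        mat = mat + mat.T
    mat /= mat.sum()
    return Glcm(matrix=mat, distance=distance, direction=tuple(direction))


def haralick(g: Glcm | np.ndarray) -> np.ndarray:
    """The 12 Haralick statistics of a normalized GLCM, in frozen order.

    Entropy uses log base 2 (zero-probability cells contribute 0).
    Correlation is defined as 0 when a marginal variance vanishes (constant
    patch).  ``variance`` is the row-marginal variance sum over the joint,
    ``sum_mean`` is (1/2) sum (i+j) p(i,j), cluster shade/tendency are the
    third/second central moments of i+j.
    """
    p = g.matrix if isinstance(g, Glcm) else np.asarray(g, dtype=float)
    if p.ndim != 2 or p.shape[0] != p.shape[1]:
        raise ValueError("GLCM must be square")
    if not np.isclose(p.sum(), 1.0, atol=1e-8):
        raise ValueError("GLCM must be normalized to sum 1")
    n = p.shape[0]
    i = np.arange(n, dtype=float)[:, None]
    j = np.arange(n, dtype=float)[None, :]

    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = float(np.sum(np.arange(n) * px))
    mu_y = float(np.sum(np.arange(n) * py))
    var_x = float(np.sum((np.arange(n) - mu_x) ** 2 * px))
    var_y = float(np.sum((np.arange(n) - mu_y) ** 2 * py))

    energy = float(np.sum(p**2))
    nz = p[p > 0]
    entropy = float(-np.sum(nz * np.log2(nz)))
    if var_x > 0 and var_y > 0:
        correlation = float(np.sum((i - mu_x) * (j - mu_y) * p) / np.sqrt(var_x * var_y))
    else:
        correlation = 0.0
    diff2 = (i - j) ** 2
    contrast = float(np.sum(diff2 * p))
    homogeneity = float(np.sum(p / (1.0 + np.abs(i - j))))
    variance = float(np.sum((i - mu_x) ** 2 * p))
    sum_mean = float(0.5 * np.sum((i + j) * p))
    idm = float(np.sum(p / (1.0 + diff2)))
    inertia = contrast  # identical sums; both slots kept by convention
    dev = i + j - mu_x - mu_y
    cluster_shade = float(np.sum(dev**3 * p))
    cluster_tendency = float(np.sum(dev**2 * p))
    max_probability = float(p.max())

    return np.array(
        [
            energy,
            entropy,
            correlation,
            contrast,
            homogeneity,
            variance,
            sum_mean,
            idm,
            inertia,
            cluster_shade,
            cluster_tendency,
            max_probability,
        ]
    )


def cooc_features(
    patch: np.ndarray, config: GlcmConfig = GlcmConfig()
) -> np.ndarray:
    """780-dimensional co-occurrence descriptor of a 3D HU patch.

    13 directions x 5 distances x 12 statistics, direction-major ordering.
    """
    levels = quantize(patch, config)
    feats = np.empty(
        len(config.directions) * len(config.distances) * len(HARALICK_NAMES)
    )
    k = 0
    for direction in config.directions:
        for distance in config.distances:
            g = glcm(levels, direction, distance, config.n_levels, config.symmetric)
            feats[k : k + 12] = haralick(g)
            k += 12
    return feats


def cooc_feature_names(config: GlcmConfig = GlcmConfig()) -> list[str]:
    """Column names matching :func:`cooc_features` ordering."""
    names = []
    for direction in config.directions:
        dtag = "(" + ",".join(str(c) for c in direction) + ")"
        for distance in config.distances:
            for stat in HARALICK_NAMES:
                names.append(f"cooc_d{distance}_dir{dtag}_{stat}")
    return names
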