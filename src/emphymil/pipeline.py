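"""Patch sampling, nested cross-validation and posterior slice maps.

This module stitches the toolkit together: random 41^3 patches are sampled
inside the lung mask of every subject (50 per scan by default), described by
texture features, grouped into bags with a weak label, and fed to a MIL
classifier inside a nested stratified cross-validation (4 outer folds for
evaluation, 3 inner folds for hyper-parameter selection by mean bag AUC with
Separability breaking ties).  Fitted models can then be painted back onto a
subject as a posterior slice map: every 10th voxel of selected axial slices
is classified and thresholded at 0.5 into emphysema / healthy grid points.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from . import miles, misvm
from .cooc import GlcmConfig, cooc_features
from .gaussbank import BinningModel, GaussBankConfig, gauss_features
from .metrics import bag_auc, dice, separability
from .mil import Bag, Instance, KernelSpec, MILParams
from .phantom import SyntheticSubject

__all__ = [
    "SamplingConfig",
    "CVConfig",
    "SliceMapConfig",
    "PosteriorSliceMap",
    "EvalReport",
    "TrainedMILModel",
    "default_parameter_grid",
    "sample_patch_centers",
    "extract_patch",
    "subject_bag",
    "cohort_bags",
    "gauss_extractor",
    "cooc_extractor",
    "combined_extractor",
    "nested_cv",
    "slice_posterior_map",
    "quantify_emphysema",
]

FeatureFn = Callable[[np.ndarray, np.ndarray], np.ndarray]


@dataclass(frozen=True)
class SamplingConfig:
    n_patches: int = 50
    patch_size: int = 41
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patches < 1 or self.patch_size < 3:
            raise ValueError("invalid sampling configuration")


@dataclass(frozen=True)
class CVConfig:
    outer_folds: int = 4
    inner_folds: int = 3
    stratified: bool = True
    seed: int = 0


@dataclass(frozen=True)
class SliceMapConfig:
    n_slices: int = 10
    slice_spacing: int = 25
    voxel_stride: int = 10
    edge_exclusion_frac: float = 0.10  # top/bottom share of lung slices skipped
    posterior_threshold: float = 0.5
    patch_size: int = 41

    def __post_init__(self) -> None:
        if self.n_slices < 1 or self.slice_spacing < 1 or self.voxel_stride < 1:
            raise ValueError("invalid slice map configuration")


def default_parameter_grid(qs: Sequence[float] = (0.25, 0.5, 0.75, 0.9, 1.0)) -> list[MILParams]:
    """The customary hyper-parameter grid: polynomial p in {1, 2}, RBF
    bandwidth in {8..20}, C in {0.001..1}, quantile q in {0.25..1}."""
    kernels = [KernelSpec("polynomial", degree=p) for p in (1, 2)]
    kernels += [KernelSpec("rbf", bandwidth=b) for b in (8, 10, 12, 14, 16, 20)]
    cs = (0.001, 0.003, 0.01, 0.03, 0.1, 0.3, 1.0)
    return [
        MILParams(kernel=k, C=c, q=q) for k in kernels for c in cs for q in qs
    ]


# ---------------------------------------------------------------------------
# patch sampling and feature extraction


def sample_patch_centers(
    lung_mask: np.ndarray, config: SamplingConfig
) -> np.ndarray:
    """Uniform random patch centers: in-mask voxels whose full patch fits
    inside the volume.  Sampled with replacement (patches may overlap);
    deterministic given the seed."""
    mask = np.asarray(lung_mask).astype(bool)
    half = config.patch_size // 2
    valid = np.zeros_like(mask)
    sl = tuple(slice(half, s - half) for s in mask.shape)
    if any(s.stop <= s.start for s in sl):
        raise ValueError("volume too small to host a patch")
    valid[sl] = mask[sl]
    centers = np.argwhere(valid)
    if len(centers) == 0:
        raise ValueError("lung mask admits no valid patch center")
    rng = np.random.default_rng(config.seed)
    picks = rng.integers(0, len(centers), size=config.n_patches)
    return centers[picks]


def extract_patch(
    volume: np.ndarray, center: Sequence[int], size: int
) -> tuple[np.ndarray, tuple[slice, slice, slice]]:
    """Size^3 window around ``center``, clipped at the volume border."""
    half = size // 2
    slices = tuple(
        slice(max(int(c) - half, 0), min(int(c) + half + 1, s))
        for c, s in zip(center, volume.shape)
    )
    return volume[slices], slices


def gauss_extractor(config: GaussBankConfig, binning: BinningModel) -> FeatureFn:
    """Filter-bank extractor with per-subject response caching (see
    :class:`emphymil.gaussbank.VolumeGaussExtractor`)."""
    from .gaussbank import VolumeGaussExtractor

    return VolumeGaussExtractor(config, binning)


def _features_at(
    extractor: FeatureFn,
    subject: SyntheticSubject | None,
    patch: np.ndarray,
    slices: tuple[slice, ...],
    mask: np.ndarray,
) -> np.ndarray:
    """Dispatch to a subject-caching extractor when available."""
    fa = getattr(extractor, "features_at", None)
    if fa is not None and subject is not None:
        return fa(subject, slices, mask)
    return extractor(patch, mask)


def cooc_extractor(config: GlcmConfig = GlcmConfig()) -> FeatureFn:
    def fn(patch: np.ndarray, mask: np.ndarray) -> np.ndarray:
        return cooc_features(patch, config)

    return fn


class combined_extractor:
    """Concatenates several extractors, forwarding subject caching."""

    def __init__(self, *fns: FeatureFn) -> None:
        self.fns = fns

    def __call__(self, patch: np.ndarray, mask: np.ndarray) -> np.ndarray:
        return np.concatenate([f(patch, mask) for f in self.fns])

    def features_at(self, subject, slices, mask):
        patch = subject.volume[slices]
        return np.concatenate(
            [_features_at(f, subject, patch, slices, mask) for f in self.fns]
        )


def subject_bag(
    subject: SyntheticSubject,
    feature_fn: FeatureFn,
    sampling: SamplingConfig,
    label_channel: Literal["copd", "dlco"],
) -> Bag:
    """Sample patches from one subject and assemble its labeled bag.

    Patch sampling depends only on the lung mask and the sampling seed, never
    on the label channel, so switching COPD <-> DLCO relabels bags without
    touching features.
    """
    centers = sample_patch_centers(subject.lung_mask, sampling)
    instances = []
    for c in centers:
        patch, slices = extract_patch(subject.volume, c, sampling.patch_size)
        pmask = subject.lung_mask[slices]
        instances.append(
            Instance(
                features=_features_at(feature_fn, subject, patch, slices, pmask),
                subject_id=subject.subject_id,
                patch_center=tuple(int(v) for v in c),
            )
        )
    label = subject.label_copd if label_channel == "copd" else subject.label_dlco
    return Bag(instances=instances, label=label, label_channel=label_channel)


def cohort_bags(
    subjects: Sequence[SyntheticSubject],
    feature_fn: FeatureFn,
    sampling: SamplingConfig,
    label_channel: Literal["copd", "dlco"],
) -> list[Bag]:
    """Bags for a cohort; per-subject sampling seeds split from the master."""
    seq = np.random.SeedSequence(sampling.seed)
    children = seq.spawn(len(subjects))
    bags = []
    for subject, child in zip(subjects, children):
        sub_cfg = SamplingConfig(
            n_patches=sampling.n_patches,
            patch_size=sampling.patch_size,
            seed=int(child.generate_state(1)[0] % (2**31)),
        )
        bags.append(subject_bag(subject, feature_fn, sub_cfg, label_channel))
    return bags


# ---------------------------------------------------------------------------
# classifiers behind one interface

_CLASSIFIERS = {
    "misvm-q": (misvm.fit, misvm.predict_bag, misvm.predict_instances),
    "miles-q": (miles.fit, miles.predict_bag, miles.predict_instances),
}


@dataclass
class TrainedMILModel:
    """A fitted MIL classifier exposing bag and instance posteriors."""

    classifier: str
    model: object
    params: MILParams

    @classmethod
    def fit(cls, classifier: str, bags: list[Bag], params: MILParams) -> "TrainedMILModel":
        if classifier not in _CLASSIFIERS:
            raise ValueError(f"unknown classifier {classifier!r}; use one of {sorted(_CLASSIFIERS)}")
        fit_fn = _CLASSIFIERS[classifier][0]
        return cls(classifier=classifier, model=fit_fn(bags, params), params=params)

    def predict_bag(self, bag: Bag) -> float:
        return _CLASSIFIERS[self.classifier][1](self.model, bag)

    def predict_instances(self, bag: Bag) -> np.ndarray:
        return _CLASSIFIERS[self.classifier][2](self.model, bag)


# ---------------------------------------------------------------------------
# nested cross-validation


@dataclass
class EvalReport:
    fold_auc: list[float]
    fold_separability: list[float]
    fold_params: list[MILParams]
    fold_test_subjects: list[list[str]]
    fold_models: list["TrainedMILModel"] = field(default_factory=list)

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.fold_auc))

    @property
    def sd_auc(self) -> float:
        return float(np.std(self.fold_auc))

    @property
    def mean_separability(self) -> float:
        return float(np.mean(self.fold_separability))

    def summary(self) -> str:
        """Human-readable summary; AUC and S scaled x100 for display."""
        lines = [
            f"bag AUC : {100 * self.mean_auc:.1f} +/- {100 * self.sd_auc:.1f}",
            f"S       : {100 * self.mean_separability:.1f}",
        ]
        for i, (a, s, p) in enumerate(
            zip(self.fold_auc, self.fold_separability, self.fold_params)
        ):
            lines.append(
                f"  fold {i}: AUC={100 * a:.1f} S={100 * s:.1f} "
                f"kernel={p.kernel.family} C={p.C:g} q={p.q:g}"
            )
        return "\n".join(lines)


def _score_model(model: TrainedMILModel, bags: list[Bag]) -> tuple[float, float]:
    """(bag AUC, Separability) of a fitted model on held-out bags."""
    post = np.array([model.predict_bag(b) for b in bags])
    labels = np.array([b.label for b in bags])
    auc = bag_auc(post, labels)
    pos = [model.predict_instances(b) for b in bags if b.label == 1]
    neg = [model.predict_instances(b) for b in bags if b.label == -1]
    s = separability(pos, neg)
    return auc, s


def nested_cv(
    bags: list[Bag],
    classifier: str = "misvm-q",
    cv: CVConfig = CVConfig(),
    grid: Sequence[MILParams] | None = None,
) -> EvalReport:
    """Nested stratified cross-validation at the subject level.

    Outer folds evaluate; inner folds select hyper-parameters by mean bag
    AUC, ties broken by larger mean Separability.  A subject's patches never
    span folds because folding acts on whole bags.
    """
    if grid is None:
        grid = default_parameter_grid()
    y = np.array([b.label for b in bags])
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")

    outer = StratifiedKFold(n_splits=cv.outer_folds, shuffle=True, random_state=cv.seed)
    fold_auc, fold_sep, fold_params, fold_subjects, fold_models = [], [], [], [], []
    for k, (tr_idx, te_idx) in enumerate(outer.split(np.zeros(len(bags)), y)):
        train = [bags[i] for i in tr_idx]
        test = [bags[i] for i in te_idx]
        if len(np.unique(y[te_idx])) < 2 or len(np.unique(y[tr_idx])) < 2:
            raise ValueError(f"outer fold {k} lacks one of the classes")

        best: tuple[float, float, MILParams] | None = None
        inner = StratifiedKFold(
            n_splits=cv.inner_folds, shuffle=True, random_state=cv.seed + 1 + k
        )
        y_tr = y[tr_idx]
        inner_splits = list(inner.split(np.zeros(len(train)), y_tr))
        for params in grid:
            aucs, seps = [], []
            for itr, ite in inner_splits:
                m = TrainedMILModel.fit(classifier, [train[i] for i in itr], params)
                a, s = _score_model(m, [train[i] for i in ite])
                aucs.append(a)
                seps.append(s)
            cand = (float(np.mean(aucs)), float(np.mean(seps)), params)
            if best is None or (cand[0], cand[1]) > (best[0], best[1]):
                best = cand
        assert best is not None
        final = TrainedMILModel.fit(classifier, train, best[2])
        a, s = _score_model(final, test)
        fold_auc.append(a)
        fold_sep.append(s)
        fold_params.append(best[2])
        fold_subjects.append([b.subject_id for b in test])
        fold_models.append(final)
    return EvalReport(
        fold_auc=fold_auc,
        fold_separability=fold_sep,
        fold_params=fold_params,
        fold_test_subjects=fold_subjects,
        fold_models=fold_models,
    )


# ---------------------------------------------------------------------------
# posterior slice maps


@dataclass
class PosteriorSliceMap:
    """Per-grid-point posteriors on sampled axial slices.

    ``points`` columns: slice (z index), x, y, posterior, label (posterior
    strictly above the threshold), lesion_truth (ground truth at the grid
    point when a lesion mask was supplied).
    """

    points: pd.DataFrame
    threshold: float = 0.5

    @property
    def pct_emphysema(self) -> float:
        """Percentage of positive grid points (strict > threshold)."""
        if len(self.points) == 0:
            raise ValueError("empty slice map")
        return float(100.0 * self.points["label"].mean())

    def per_slice_pct(self) -> pd.Series:
        return 100.0 * self.points.groupby("slice")["label"].mean()

    def dice_vs_truth(self) -> float:
        """Dice between predicted-positive and true-lesion grid points."""
        if "lesion_truth" not in self.points:
            raise ValueError("slice map carries no ground truth")
        return dice(
            self.points["label"].to_numpy(), self.points["lesion_truth"].to_numpy()
        )


def _select_slices(lung_mask: np.ndarray, config: SliceMapConfig) -> list[int]:
    zs = np.flatnonzero(lung_mask.any(axis=(0, 1)))
    if zs.size == 0:
        raise ValueError("no lung-containing slices")
    drop = int(round(config.edge_exclusion_frac * zs.size))
    eligible = zs[drop : zs.size - drop] if zs.size > 2 * drop else zs
    if eligible.size < config.n_slices:
        raise ValueError("fewer eligible slices than requested")
    span = (config.n_slices - 1) * config.slice_spacing
    if span >= eligible.size:
        raise ValueError(
            "slice spacing does not fit the eligible lung extent; "
            "reduce n_slices or slice_spacing"
        )
    start = (eligible.size - 1 - span) // 2
    return [int(eligible[start + i * config.slice_spacing]) for i in range(config.n_slices)]


def slice_posterior_map(
    model: TrainedMILModel,
    subject: SyntheticSubject,
    feature_fn: FeatureFn,
    config: SliceMapConfig = SliceMapConfig(),
) -> PosteriorSliceMap:
    """Classify a regular grid of in-mask voxels on sampled axial slices.

    Every ``voxel_stride``-th voxel in both in-plane directions is visited;
    grid points whose patch is clipped by the volume border are kept only if
    at least half of the clipped window lies inside the lung mask.  All grid
    points of the subject form one pseudo-bag so bag-context instance scoring
    (MILES-Q) is well defined.
    """
    slices_z = _select_slices(subject.lung_mask, config)
    size = config.patch_size
    half = size // 2
    rows = []
    feats = []
    for z in slices_z:
        mask2d = subject.lung_mask[:, :, z]
        xs = np.arange(0, mask2d.shape[0], config.voxel_stride)
        ys = np.arange(0, mask2d.shape[1], config.voxel_stride)
        for x in xs:
            for y in ys:
                if not mask2d[x, y]:
                    continue
                patch, sl = extract_patch(subject.volume, (x, y, z), size)
                pmask = subject.lung_mask[sl]
                clipped = patch.size < size**3
                if clipped and pmask.mean() < 0.5:
                    continue
                feats.append(_features_at(feature_fn, subject, patch, sl, pmask))
                rows.append(
                    {
                        "slice": z,
                        "x": int(x),
                        "y": int(y),
                        "lesion_truth": bool(subject.lesion_mask[x, y, z]),
                    }
                )
    if not rows:
        raise ValueError("no eligible grid points")
    bag = Bag(
        instances=[
            Instance(features=f, subject_id=subject.subject_id) for f in feats
        ],
        label=None,
    )
    post = model.predict_instances(bag)
    df = pd.DataFrame(rows)
    df["posterior"] = post
    df["label"] = df["posterior"] > config.posterior_threshold
    return PosteriorSliceMap(points=df, threshold=config.posterior_threshold)


def quantify_emphysema(slice_map: PosteriorSliceMap) -> dict:
    """Overall and per-slice emphysema percentage from a posterior map."""
    return {
        "pct_emphysema": slice_map.pct_emphysema,
        "per_slice_pct": slice_map.per_slice_pct().to_dict(),
        "n_grid_points": int(len(slice_map.points)),
    }
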