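"""Synthetic CT-like lung phantoms with planted low-attenuation lesions.

Each phantom is an ellipsoidal "lung" filled with spatially correlated
Gaussian texture around -850 HU (healthy parenchyma) in which, for diseased
subjects, spherical low-attenuation blobs around -975 HU are planted until a
target fraction of the lung volume is lesioned.  The realized lesion burden
drives simulated pulmonary-function covariates through fixed noisy
decreasing links:

    dlco_pct = 85 - 180 * burden + eps,   fev1_pct = 95 - 200 * burden + eps

with eps ~ Normal(0, 8), clamped to be positive.  Thresholding these
covariates reproduces the two weak labelings used downstream: COPD
(GOLD class A-D positive) and low diffusing capacity (DLCO < 60 % predicted
positive).  Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "PhantomSpec",
    "SyntheticSubject",
    "generate_subject",
    "make_cohort",
    "save_subject",
    "cohort_table",
]

_COVARIATE_NOISE_SD = 8.0
_LUNG_SEMIAXIS_FRAC = 0.42  # ellipsoid semi-axes as a fraction of grid extent


@dataclass(frozen=True)
class PhantomSpec:
    """The stated world of the simulator; see module docstring for links."""

    shape: tuple[int, int, int] = (128, 128, 128)
    spacing_mm: tuple[float, float, float] = (0.6, 0.6, 0.6)
    background_hu_mean: float = -850.0
    background_hu_sd: float = 40.0
    lesion_hu_mean: float = -975.0
    lesion_hu_sd: float = 15.0
    lesion_count_range: tuple[int, int] = (1, 400)
    lesion_radius_range_mm: tuple[float, float] = (12.0, 18.0)
    burden_target: float = 0.15
    texture_correlation_length_mm: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.lesion_hu_mean < self.background_hu_mean:
            raise ValueError("lesions must be low-attenuation (lesion mean < background mean)")
        if not 0.0 <= self.burden_target <= 1.0:
            raise ValueError("burden_target must lie in [0, 1]")
        if self.texture_correlation_length_mm <= 0:
            raise ValueError("texture correlation length must be > 0")
        if any(s < 8 for s in self.shape):
            raise ValueError("degenerate phantom shape")


@dataclass
class SyntheticSubject:
    """One simulated subject: volume, masks, covariates, labels."""

    subject_id: str
    volume: np.ndarray  # HU
    lung_mask: np.ndarray  # bool
    lesion_mask: np.ndarray  # bool, ground-truth emphysema
    spacing_mm: tuple[float, float, float]
    fev1_pct: float
    dlco_pct: float
    gold_class: str  # none / A / B / C / D

    @property
    def label_copd(self) -> int:
        """+1 if GOLD class A-D (COPD), else -1."""
        return 1 if self.gold_class != "none" else -1

    @property
    def label_dlco(self) -> int:
        """+1 if DLCO < 60 % predicted (low diffusing capacity), else -1."""
        return 1 if self.dlco_pct < 60.0 else -1

    @property
    def lesion_fraction(self) -> float:
        return float(self.lesion_mask.sum() / self.lung_mask.sum())


def _ellipsoid_mask(shape: tuple[int, int, int]) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    center = [(s - 1) / 2.0 for s in shape]
    semi = [_LUNG_SEMIAXIS_FRAC * s for s in shape]
    r2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi))
    return r2 <= 1.0


def _correlated_field(
    rng: np.random.Generator,
    shape: tuple[int, int, int],
    sd: float,
    corr_len_mm: float,
    spacing_mm: tuple[float, float, float],
) -> np.ndarray:
    """Smoothed white noise rescaled to the requested pointwise SD."""
    noise = rng.standard_normal(shape)
    sigma_vox = [corr_len_mm / h for h in spacing_mm]
    smooth = ndimage.gaussian_filter(noise, sigma_vox, mode="wrap")
    s = smooth.std()
    if s > 0:
        smooth *= sd / s
    return smooth


def _gold_from_fev1(fev1_pct: float) -> str:
    if fev1_pct >= 70:
        return "A"
    if fev1_pct >= 55:
        return "B"
    if fev1_pct >= 40:
        return "C"
    return "D"


def generate_subject(
    spec: PhantomSpec, diseased: bool, subject_id: str = "s000"
) -> SyntheticSubject:
    """Generate one phantom subject, deterministic given ``spec.seed``.

    Healthy subjects get an empty lesion mask and covariates at zero burden.
    Diseased subjects get spherical lesions placed at uniform in-lung centers
    until the realized burden reaches ``spec.burden_target``.
    """
    rng = np.random.default_rng(spec.seed)
    shape = spec.shape
    lung = _ellipsoid_mask(shape)
    lung_vox = int(lung.sum())
    if lung_vox == 0:
        raise ValueError("degenerate shape: empty lung mask")
    if spec.burden_target > 1.0:
        raise ValueError("infeasible burden_target")

    volume = spec.background_hu_mean + _correlated_field(
        rng, shape, spec.background_hu_sd, spec.texture_correlation_length_mm, spec.spacing_mm
    )

    lesion = np.zeros(shape, dtype=bool)
    if diseased and spec.burden_target > 0:
        centers = np.argwhere(lung)
        grids = np.ogrid[tuple(slice(0, s) for s in shape)]
        max_attempts = 10000
        attempts = 0
        max_lesions = spec.lesion_count_range[1]
        while (
            lesion.sum() / lung_vox < spec.burden_target
            and attempts < max_attempts
            and attempts < max_lesions
        ):
            attempts += 1
            c = centers[rng.integers(len(centers))]
            radius_mm = rng.uniform(*spec.lesion_radius_range_mm)
            # cap the radius so one blob cannot overshoot the target burden:
            # allow at most ~1.3x the remaining lesion volume in a single sphere
            remaining_vox = spec.burden_target * lung_vox - lesion.sum()
            vox_vol = float(np.prod(spec.spacing_mm))
            r_cap = (3.0 * 1.3 * max(remaining_vox, 1.0) * vox_vol / (4.0 * np.pi)) ** (1.0 / 3.0)
            radius_mm = min(radius_mm, r_cap)
            r2 = sum(
                (((g - ci) * h) ** 2)
                for g, ci, h in zip(grids, c, spec.spacing_mm)
            )
            blob = (r2 <= radius_mm**2) & lung
            lesion |= blob
        if lesion.sum() / lung_vox < spec.burden_target * 0.5:
            raise ValueError("infeasible burden_target for this lung geometry")
        # lesion texture: correlated field around the lesion mean
        lesion_field = spec.lesion_hu_mean + _correlated_field(
            rng, shape, spec.lesion_hu_sd, spec.texture_correlation_length_mm, spec.spacing_mm
        )
        volume = np.where(lesion, lesion_field, volume)

    burden = float(lesion.sum() / lung_vox)
    dlco = 85.0 - 180.0 * burden + rng.normal(0.0, _COVARIATE_NOISE_SD)
    fev1 = 95.0 - 200.0 * burden + rng.normal(0.0, _COVARIATE_NOISE_SD)
    dlco = max(dlco, 1.0)
    fev1 = max(fev1, 1.0)
    gold = _gold_from_fev1(fev1) if diseased else "none"

    return SyntheticSubject(
        subject_id=subject_id,
        volume=volume,
        lung_mask=lung,
        lesion_mask=lesion,
        spacing_mm=spec.spacing_mm,
        fev1_pct=float(fev1),
        dlco_pct=float(dlco),
        gold_class=gold,
    )


def make_cohort(
    n_healthy: int,
    n_diseased: int,
    spec: PhantomSpec = PhantomSpec(),
    seed: int = 0,
) -> list[SyntheticSubject]:
    """A reproducible cohort; per-subject seeds split from the master seed.

    Healthy subjects come first (``h000``...), then diseased (``d000``...).
    """
    if n_healthy + n_diseased < 8:
        raise ValueError("need at least 8 subjects for 4-fold cross-validation")
    seed_seq = np.random.SeedSequence(seed)
    children = seed_seq.spawn(n_healthy + n_diseased)
    subjects: list[SyntheticSubject] = []
    for i in range(n_healthy):
        sub_seed = int(children[i].generate_state(1)[0] % (2**31))
        s = replace(spec, seed=sub_seed)
        subjects.append(generate_subject(s, diseased=False, subject_id=f"h{i:03d}"))
    for i in range(n_diseased):
        sub_seed = int(children[n_healthy + i].generate_state(1)[0] % (2**31))
        s = replace(spec, seed=sub_seed)
        subjects.append(generate_subject(s, diseased=True, subject_id=f"d{i:03d}"))
    return subjects


def cohort_table(subjects: list[SyntheticSubject]) -> pd.DataFrame:
    """Covariate/label manifest for a cohort."""
    return pd.DataFrame(
        {
            "subject_id": [s.subject_id for s in subjects],
            "fev1_pct": [s.fev1_pct for s in subjects],
            "dlco_pct": [s.dlco_pct for s in subjects],
            "gold_class": [s.gold_class for s in subjects],
            "label_copd": [s.label_copd for s in subjects],
            "label_dlco": [s.label_dlco for s in subjects],
            "lesion_fraction": [s.lesion_fraction for s in subjects],
        }
    )


def save_subject(subject: SyntheticSubject, out_dir: str | Path) -> None:
    """Write volume/lung_mask/lesion_mask as NIfTI (int16 HU / uint8 masks)."""
    import nibabel as nib

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    affine = np.diag(list(subject.spacing_mm) + [1.0])
    vol = nib.Nifti1Image(np.round(subject.volume).astype(np.int16), affine)
    nib.save(vol, out / f"{subject.subject_id}_volume.nii.gz")
    for name, mask in (("lung_mask", subject.lung_mask), ("lesion_mask", subject.lesion_mask)):
        img = nib.Nifti1Image(mask.astype(np.uint8), affine)
        nib.save(img, out / f"{subject.subject_id}_{name}.nii.gz")
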