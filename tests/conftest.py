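"""Shared fixtures: 2-D toy MIL data and the strong-signal phantom cohort.

The cohort fixture is session-scoped because feature extraction over a
20-subject phantom cohort is the expensive part of the suite (~3-5 min on
one CPU); every test that needs real texture features shares it.
"""

from __future__ import annotations

import numpy as np
import pytest

from emphymil.gaussbank import (
    GaussBankConfig,
    fit_adaptive_bins,
    pooled_responses,
)
from emphymil.mil import Bag, Instance, KernelSpec, MILParams
from emphymil.phantom import PhantomSpec, make_cohort
from emphymil.pipeline import (
    CVConfig,
    SamplingConfig,
    SliceMapConfig,
    cohort_bags,
    gauss_extractor,
    nested_cv,
    slice_posterior_map,
)

LESION_CENTER = (4.0, 4.0)
BACKGROUND_CENTER = (0.0, 0.0)


def toy_bag(
    rng: np.random.Generator,
    subject_id: str,
    n_lesion: int,
    n_background: int,
    label: int,
    sd: float = 1.0,
) -> Bag:
    """2-D Gaussian toy bag: lesion concept at (4,4), background at origin."""
    parts = []
    if n_lesion:
        parts.append(rng.normal(LESION_CENTER, sd, size=(n_lesion, 2)))
    if n_background:
        parts.append(rng.normal(BACKGROUND_CENTER, sd, size=(n_background, 2)))
    X = np.vstack(parts)
    return Bag([Instance(x, subject_id) for x in X], label=label)


@pytest.fixture(scope="session")
def toy_mil_bags() -> list[Bag]:
    """5 positive bags (5 lesion + 5 background) and 5 negative (10 background)."""
    rng = np.random.default_rng(42)
    pos = [toy_bag(rng, f"p{i}", 5, 5, 1) for i in range(5)]
    neg = [toy_bag(rng, f"n{i}", 0, 10, -1) for i in range(5)]
    return pos + neg


@pytest.fixture(scope="session")
def toy_rbf_params() -> MILParams:
    return MILParams(kernel=KernelSpec("rbf", bandwidth=2.0), C=1.0, q=0.5)


# reduced hyper-parameter grid: the full customary grid (8 kernels x 7 C x 5 q)
# is a compute matter, not a correctness one; this subset spans kernel
# bandwidth, regularization and the quantile while fitting a 1-CPU budget
REDUCED_GRID = [
    MILParams(kernel=KernelSpec("rbf", bandwidth=b), C=c, q=q)
    for b in (10.0, 16.0)
    for c in (0.01, 1.0)
    for q in (0.5, 1.0)
]


@pytest.fixture(scope="session")
def strong_cohort_run():
    """Full pipeline on a 10v10 strong-contrast phantom cohort.

    Generates the cohort, fits adaptive bins on held-out reference phantoms,
    extracts Gaussian filter-bank features (50 patches of 41^3 per subject),
    runs nested 4x3 stratified CV with miSVM-Q, and paints a posterior slice
    map for a diseased subject held out of its fold's training data.
    """
    spec = PhantomSpec()  # defaults: -850/-975 HU contrast, burden 0.15
    cohort = make_cohort(10, 10, spec, seed=11)

    ref = make_cohort(4, 4, spec, seed=999)
    reference = [ref[0], ref[1], ref[4], ref[5]]  # 2 healthy + 2 diseased
    cfg = GaussBankConfig()
    resp = pooled_responses(
        [(s.volume, s.lung_mask) for s in reference], cfg,
        max_samples_per_volume=8000, seed=0,
    )
    binning = fit_adaptive_bins(resp, source="held-out synthetic reference, seed 999")
    extractor = gauss_extractor(cfg, binning)

    bags = cohort_bags(cohort, extractor, SamplingConfig(seed=5), "copd")
    report = nested_cv(bags, "misvm-q", CVConfig(seed=3), REDUCED_GRID)

    by_id = {s.subject_id: s for s in cohort}
    held_out_diseased = next(
        sid for sid in report.fold_test_subjects[0] if sid.startswith("d")
    )
    slice_map = slice_posterior_map(
        report.fold_models[0],
        by_id[held_out_diseased],
        extractor,
        SliceMapConfig(n_slices=10, slice_spacing=8, voxel_stride=10),
    )
    return {
        "spec": spec,
        "cohort": cohort,
        "binning": binning,
        "extractor": extractor,
        "bags": bags,
        "report": report,
        "slice_map": slice_map,
        "held_out_subject": held_out_diseased,
    }
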