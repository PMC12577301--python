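"""Shared fixtures and the synthetic study conditions used across the suite.

The expensive strongly-separated-cohort cross-validation results are computed
once per session and shared between the protocol-sanity test and any test
that needs trained volumetric-CNN results.
"""

from __future__ import annotations

import numpy as np
import pytest

from fogpet.pipeline import preprocess_volumes
from fogpet.synthetic import (CohortConfig, EffectSpec, calibrate_noise_sd, generate_cohort)

# Dense multi-region pattern shared by both PD groups: 16 small spheres with
# alternating hyper-/hypometabolism, all placed away from the central axial
# slice. Dense enough that the volumetric CNN separates PD from HC within a
# few epochs.
SEPARATED_CENTERS = [
    (16, 12, 10), (20, 19, 22), (12, 20, 10), (20, 13, 21),
    (12, 15, 22), (18, 20, 9), (15, 18, 23), (21, 16, 11),
    (13, 12, 20), (17, 14, 9), (11, 17, 21), (19, 17, 23),
    (14, 21, 20), (18, 11, 12), (10, 14, 12), (22, 18, 13),
]

# Sparse variant for the model-ordering comparison: fewer, smaller spheres,
# still off the central slice, so slice- and downsample-based baselines lose
# most of the discriminative signal while the full-resolution 3D model keeps it.
SPARSE_CENTERS = SEPARATED_CENTERS[:12]


def _pattern_config(centers, radius: float, amplitude: float, seed: int,
                    target_d: float) -> CohortConfig:
    eff = []
    for i, c in enumerate(centers):
        frac = amplitude if i % 2 == 0 else -amplitude
        for g in ("PD-FOG", "PD-NFOG"):
            eff.append(EffectSpec(region_center=c, region_radius=radius, group=g,
                                  effect_fraction=frac))
    cfg = CohortConfig(effects=eff, seed=seed)
    sd = calibrate_noise_sd(cfg, 0, fwhm_mm=10.0, target_d=target_d)
    return cfg.model_copy(update={"noise_sd": sd})


def separated_cohort_config(seed: int = 7, target_d: float = 2.0) -> CohortConfig:
    """The strongly separated condition: a dense 16-sphere metabolic pattern
    shared by both PD groups, noise calibrated to voxel-wise d ~ 2 after
    preprocessing."""
    return _pattern_config(SEPARATED_CENTERS, radius=2.5, amplitude=0.35,
                           seed=seed, target_d=target_d)


def sparse_cohort_config(seed: int = 11, target_d: float = 2.0) -> CohortConfig:
    """A sparser, finer-grained 12-sphere pattern for the model-family
    comparison: the signal survives at full 3D resolution but is heavily
    attenuated by 16^3 block-averaging and absent from the central slice."""
    return _pattern_config(SPARSE_CENTERS, radius=2.0, amplitude=0.3,
                           seed=seed, target_d=target_d)


@pytest.fixture(scope="session")
def separated_cohort():
    """One preprocessed strongly separated cohort (46 subjects, 32^3)."""
    cfg = separated_cohort_config(seed=7)
    records, volumes, truth = generate_cohort(cfg)
    processed = preprocess_volumes(volumes, fwhm_mm=10.0, target=1.0)
    return records, processed, truth


@pytest.fixture(scope="session")
def sparse_cohort():
    """One preprocessed sparse fine-grained cohort (46 subjects, 32^3)."""
    cfg = sparse_cohort_config(seed=11)
    records, volumes, truth = generate_cohort(cfg)
    processed = preprocess_volumes(volumes, fwhm_mm=10.0, target=1.0)
    return records, processed, truth


@pytest.fixture(scope="session")
def cnn_cv_reports(separated_cohort):
    """10-fold CV of the 3D CNN on the separated cohort for five seeds.

    Computed once per session; shared by the protocol-sanity assertions.
    """
    from fogpet.baselines import build_baselines
    from fogpet.cv import run_cv, select_task
    from fogpet.nn import TrainConfig

    records, processed, _ = separated_cohort
    idx, y = select_task(records, "pd_vs_hc")
    vols = [processed[i] for i in idx]
    ids = [records[i].id for i in idx]
    reports = []
    for seed in range(5):
        factory = lambda fold_seed: build_baselines("cnn3d", train_cfg=TrainConfig())
        reports.append(run_cv(vols, np.asarray(y), factory, task_kind="classify",
                              k=10, seed=seed, subject_ids=ids,
                              task_name="pd_vs_hc", model_name="cnn3d"))
    return reports
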