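"""Synthetic PET-like cohort generation with known ground truth.

Real resting-state FDG-PET cohorts of the kind this package analyses (healthy
controls plus Parkinson's disease patients with and without freezing of gait)
are rarely shareable, so every downstream stage is exercised on simulated
cohorts whose regional effects, confounding structure, and questionnaire
coupling are known exactly.

A subject's image is

    subject_scale * (baseline + sum of group effects) + white Gaussian noise

inside an ellipsoidal brain mask, zero outside. The baseline is a smooth
radial gradient (higher centrally, as in gray-matter-dominated FDG uptake),
so that global-mean intensity normalization is a non-trivial operation. The
per-subject multiplicative ``subject_scale`` (log-normal) emulates the
dose/habitus uptake variability that normalization must remove. Group effects
are spherical regions of hyper- or hypometabolism expressed as a signed
fraction of the local baseline.

Freezing-of-gait questionnaire (FOG-Q) totals are built as a clipped linear
function of realized (noisy, normalization-scale-free) regional means plus
motor severity (UPDRS-III) and medication dose (LEDD) contributions and
noise; both covariates are drawn group-dependently so that disease severity
confounds the region-score relationship, which is exactly what the partial
correlation stage has to remove.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .volume import Volume, gaussian_smooth, normalize_global_mean, write_volume

__all__ = [
    "GROUPS",
    "EffectSpec",
    "CovariateModel",
    "FogqModel",
    "CohortConfig",
    "SubjectRecord",
    "CohortGroundTruth",
    "ConfigurationError",
    "ellipsoid_brain_mask",
    "radial_baseline",
    "sphere_mask",
    "generate_cohort",
    "write_cohort",
    "calibrate_noise_sd",
    "smoothing_noise_factor",
    "fogq_weight_for_partial_r",
    "simulate_partial_corr_draw",
    "simulate_confounded_draw",
    "default_cohort_config",
]

GROUPS = ("HC", "PD-NFOG", "PD-FOG")
Group = Literal["HC", "PD-NFOG", "PD-FOG"]


class ConfigurationError(ValueError):
    """Invalid cohort configuration."""


class EffectSpec(BaseModel):
    """A spherical regional effect planted for one group.

    ``effect_fraction`` is a signed unitless fraction of the local baseline:
    +0.20 means 20% hypermetabolism within the sphere for that group.
    """

    model_config = ConfigDict(extra="forbid")

    region_center: tuple[int, int, int]
    region_radius: float = Field(ge=1.0)
    group: Group
    effect_fraction: float = Field(gt=-1.0)


class CovariateModel(BaseModel):
    """Group-dependent normal draws (clipped at 0) for UPDRS-III and LEDD.

    Defaults are calibrated to the clinical characteristics of the cohort
    this generator emulates: PD-FOG patients are more severely affected and
    more heavily medicated than PD-NFOG in expectation, so both covariates
    confound any region-score association.
    """

    model_config = ConfigDict(extra="forbid")

    updrs3_mean: dict[str, float] = Field(
        default_factory=lambda: {"HC": 2.0, "PD-NFOG": 13.36, "PD-FOG": 21.72}
    )
    updrs3_sd: dict[str, float] = Field(
        default_factory=lambda: {"HC": 2.0, "PD-NFOG": 8.30, "PD-FOG": 9.83}
    )
    ledd_mean: dict[str, float] = Field(
        default_factory=lambda: {"HC": 0.0, "PD-NFOG": 136.36, "PD-FOG": 321.39}
    )
    ledd_sd: dict[str, float] = Field(
        default_factory=lambda: {"HC": 0.0, "PD-NFOG": 181.35, "PD-FOG": 217.09}
    )


class FogqModel(BaseModel):
    """Linear model generating FOG-Q totals (clipped to [0, 24]; HC forced 0).

    ``roi_weights`` maps an index into ``CohortConfig.effects`` to a weight on
    that subject's realized normalized mean over the corresponding sphere.
    """

    model_config = ConfigDict(extra="forbid")

    intercept: float = -35.6
    roi_weights: dict[int, float] = Field(default_factory=dict)
    updrs3_weight: float = 0.15
    ledd_weight: float = 0.004
    noise_sd: float = Field(default=3.0, ge=0.0)


class CohortConfig(BaseModel):
    """Full specification of a synthetic cohort."""

    model_config = ConfigDict(extra="forbid")

    grid_shape: tuple[int, int, int] = (32, 32, 32)
    voxel_size_mm: tuple[float, float, float] = (4.0, 4.0, 4.0)
    mask_semi_axes: tuple[float, float, float] = (12.0, 14.0, 12.0)
    group_sizes: dict[str, int] = Field(
        default_factory=lambda: {"HC": 17, "PD-NFOG": 11, "PD-FOG": 18}
    )
    effects: list[EffectSpec] = Field(default_factory=list)
    baseline_peak: float = Field(default=100.0, gt=0.0)
    baseline_edge_fraction: float = Field(default=0.6, gt=0.0, le=1.0)
    # default white-noise SD calibrated so the post-normalization, post-10-mm-
    # smoothing voxel-wise Cohen's d inside the reference FOG hypermetabolic
    # sphere is ~1.5 (see calibrate_noise_sd)
    noise_sd: float = Field(default=39.4, ge=0.0)
    subject_scale_sd: float = Field(default=0.1, ge=0.0)
    covariates: CovariateModel = Field(default_factory=CovariateModel)
    fogq: FogqModel = Field(default_factory=FogqModel)
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "CohortConfig":
        if any(s <= 0 for s in self.grid_shape):
            raise ConfigurationError("grid_shape entries must be positive")
        for g, n in self.group_sizes.items():
            if g not in GROUPS:
                raise ConfigurationError(f"unknown group {g!r}")
            if n < 0:
                raise ConfigurationError(f"group_sizes[{g!r}] must be >= 0, got {n}")
        for k in self.fogq.roi_weights:
            if not (0 <= k < len(self.effects)):
                raise ConfigurationError(
                    f"fogq.roi_weights index {k} out of range for {len(self.effects)} effects"
                )
        return self


@dataclasses.dataclass
class SubjectRecord:
    """One subject's label and clinical scores."""

    id: str
    group: str
    fogq: float
    updrs3: float
    ledd: float
    volume_path: str | None = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ConfigurationError(f"unknown group {self.group!r}")
        if self.group == "HC" and self.fogq != 0:
            raise ConfigurationError("HC subjects must have fogq == 0")


@dataclasses.dataclass
class CohortGroundTruth:
    """Everything a recovery test needs to score the pipeline."""

    effect_masks: list[np.ndarray]  # one boolean grid per EffectSpec
    effect_specs: list[EffectSpec]
    fogq_model: FogqModel
    roi_means: pd.DataFrame  # subjects x effects, realized normalized means
    subject_scales: np.ndarray

    def to_json_dict(self) -> dict:
        return {
            "effects": [e.model_dump() for e in self.effect_specs],
            "fogq_model": self.fogq_model.model_dump(),
            "effect_sizes_voxels": [int(m.sum()) for m in self.effect_masks],
            "roi_means": self.roi_means.round(6).to_dict(orient="index"),
            "subject_scales": [float(s) for s in self.subject_scales],
        }


def _center(grid_shape) -> np.ndarray:
    return (np.asarray(grid_shape, dtype=float) - 1.0) / 2.0


def _normalized_radius(grid_shape, semi_axes) -> np.ndarray:
    """Per-voxel ellipsoidal radius rho (rho <= 1 is inside)."""
    c = _center(grid_shape)
    axes = np.asarray(semi_axes, dtype=float)
    coords = np.indices(grid_shape, dtype=float)
    return np.sqrt(sum(((coords[a] - c[a]) / axes[a]) ** 2 for a in range(3)))


def ellipsoid_brain_mask(grid_shape, semi_axes, voxel_size_mm=(1.0, 1.0, 1.0)) -> Volume:
    """Binary ellipsoidal brain mask centered on the grid.

    A voxel is in the mask iff sum(((v - c) / a)^2) <= 1. The mask is exactly
    symmetric under reflection through the grid center.
    """
    semi_axes = np.asarray(semi_axes, dtype=float)
    if np.any(semi_axes <= 0):
        raise ConfigurationError(f"semi_axes must be positive, got {tuple(semi_axes)}")
    if np.any(2 * semi_axes > np.asarray(grid_shape)):
        raise ConfigurationError(
            f"semi_axes {tuple(semi_axes)} do not fit in grid {tuple(grid_shape)}"
        )
    mask = _normalized_radius(grid_shape, semi_axes) <= 1.0
    affine = np.diag([*voxel_size_mm, 1.0])
    return Volume(data=mask.astype(np.float32), affine=affine, mask=mask)


def radial_baseline(grid_shape, semi_axes, peak: float, edge_fraction: float) -> np.ndarray:
    """Smooth radial baseline: ``peak`` at the center, ``peak*edge_fraction`` at
    the mask edge, quadratic in the ellipsoidal radius. Zero outside the mask."""
    rho = _normalized_radius(grid_shape, semi_axes)
    base = peak * (1.0 - (1.0 - edge_fraction) * np.clip(rho, 0.0, 1.0) ** 2)
    return np.where(rho <= 1.0, base, 0.0)


def sphere_mask(grid_shape, center, radius) -> np.ndarray:
    """Boolean sphere (Euclidean, voxel units) on the grid."""
    coords = np.indices(grid_shape, dtype=float)
    c = np.asarray(center, dtype=float)
    d2 = sum((coords[a] - c[a]) ** 2 for a in range(3))
    return d2 <= float(radius) ** 2


def _effect_images(config: CohortConfig, mask: np.ndarray, baseline: np.ndarray):
    """Per-spec additive effect image and boolean region mask; validates that
    every region lies fully inside the brain mask."""
    images, masks = [], []
    for i, spec in enumerate(config.effects):
        region = sphere_mask(config.grid_shape, spec.region_center, spec.region_radius)
        if not region.any():
            raise ConfigurationError(f"effects[{i}]: empty region")
        if np.any(region & ~mask):
            raise ConfigurationError(
                f"effects[{i}]: region at {spec.region_center} r={spec.region_radius} "
                "extends outside the brain mask"
            )
        images.append(np.where(region, spec.effect_fraction * baseline, 0.0))
        masks.append(region)
    return images, masks


def generate_cohort(config: CohortConfig):
    """Generate a full synthetic cohort.

    Returns
    -------
    records : list of SubjectRecord
    volumes : list of Volume (raw, unnormalized, unsmoothed; mask attached)
    truth : CohortGroundTruth
    """
    rng = np.random.default_rng(config.seed)
    mask_vol = ellipsoid_brain_mask(config.grid_shape, config.mask_semi_axes, config.voxel_size_mm)
    mask = mask_vol.mask
    baseline = radial_baseline(
        config.grid_shape, config.mask_semi_axes, config.baseline_peak, config.baseline_edge_fraction
    )
    effect_imgs, effect_masks = _effect_images(config, mask, baseline)

    group_effect = {
        g: baseline + sum(
            (img for img, s in zip(effect_imgs, config.effects) if s.group == g), np.zeros_like(baseline)
        )
        for g in GROUPS
    }

    records: list[SubjectRecord] = []
    volumes: list[Volume] = []
    scales: list[float] = []
    roi_rows: list[dict] = []
    cov = config.covariates

    idx = 0
    for g in GROUPS:
        n = config.group_sizes.get(g, 0)
        for _ in range(n):
            sid = f"sub-{idx:03d}"
            scale = float(np.exp(rng.normal(0.0, config.subject_scale_sd)))
            noise = rng.normal(0.0, config.noise_sd, size=config.grid_shape)
            data = np.where(mask, scale * group_effect[g] + noise, 0.0)
            vol = Volume(data=data, affine=np.diag([*config.voxel_size_mm, 1.0]), mask=mask)

            # Realized scale-free regional means: what normalization recovers.
            gmean = data[mask].mean()
            roi_means = {j: float(data[m].mean() / gmean) for j, m in enumerate(effect_masks)}

            updrs3 = float(max(0.0, rng.normal(cov.updrs3_mean[g], cov.updrs3_sd[g])))
            ledd = float(max(0.0, rng.normal(cov.ledd_mean[g], cov.ledd_sd[g])))
            if g == "HC":
                fogq = 0.0
            else:
                fq = config.fogq.intercept
                fq += sum(w * roi_means[j] for j, w in config.fogq.roi_weights.items())
                fq += config.fogq.updrs3_weight * updrs3 + config.fogq.ledd_weight * ledd
                fq += rng.normal(0.0, config.fogq.noise_sd)
                fogq = float(np.clip(fq, 0.0, 24.0))

            records.append(SubjectRecord(id=sid, group=g, fogq=fogq, updrs3=updrs3, ledd=ledd))
            volumes.append(vol)
            scales.append(scale)
            roi_rows.append(roi_means)
            idx += 1

    roi_df = pd.DataFrame(roi_rows, index=[r.id for r in records])
    roi_df.columns = [f"effect_{j}" for j in roi_df.columns]
    truth = CohortGroundTruth(
        effect_masks=effect_masks,
        effect_specs=list(config.effects),
        fogq_model=config.fogq,
        roi_means=roi_df,
        subject_scales=np.asarray(scales),
    )
    return records, volumes, truth


def write_cohort(records, volumes, truth: CohortGroundTruth, outdir) -> Path:
    """Write a cohort to disk: NIfTI volumes, a clinical TSV, ground-truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec, vol in zip(records, volumes):
        path = outdir / f"{rec.id}.nii.gz"
        write_volume(vol, path)
        rec.volume_path = str(path)
        rows.append(dataclasses.asdict(rec))
    pd.DataFrame(rows).to_csv(outdir / "clinical.tsv", sep="\t", index=False)
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(truth.to_json_dict(), fh, indent=1)
    return outdir


# ---------------------------------------------------------------------------
# Calibration helpers
# ---------------------------------------------------------------------------

def smoothing_noise_factor(grid_shape, voxel_size_mm, fwhm_mm: float) -> float:
    """SD shrinkage factor for white noise passed through the smoothing kernel.

    Equal to sqrt(sum of squared discrete kernel weights), evaluated
    numerically by smoothing a centered unit impulse on the given grid.
    """
    if fwhm_mm == 0:
        return 1.0
    impulse = np.zeros(grid_shape, dtype=np.float64)
    impulse[tuple(s // 2 for s in grid_shape)] = 1.0
    vol = Volume(data=impulse, affine=np.diag([*voxel_size_mm, 1.0]))
    sm = gaussian_smooth(vol, fwhm_mm).data.astype(np.float64)
    return float(np.sqrt((sm**2).sum()))


def calibrate_noise_sd(
    config: CohortConfig, effect_index: int, fwhm_mm: float, target_d: float
) -> float:
    """White-noise SD so that the post-normalization, post-smoothing voxel-wise
    Cohen's d inside the given planted region is approximately ``target_d``.

    Works on noiseless prototypes: the affected-group and reference images are
    normalized and smoothed exactly as the analysis pipeline would, giving the
    realized mean difference inside the region; white noise of SD s becomes
    smoothed noise of SD (s / global_mean) * kappa after the same pipeline,
    with kappa from :func:`smoothing_noise_factor`.
    """
    if target_d <= 0:
        raise ConfigurationError("target_d must be positive")
    spec = config.effects[effect_index]
    mask_vol = ellipsoid_brain_mask(config.grid_shape, config.mask_semi_axes, config.voxel_size_mm)
    baseline = radial_baseline(
        config.grid_shape, config.mask_semi_axes, config.baseline_peak, config.baseline_edge_fraction
    )
    effect_imgs, effect_masks = _effect_images(config, mask_vol.mask, baseline)
    region = effect_masks[effect_index]
    group_imgs = {g: baseline.copy() for g in GROUPS}
    for img, s in zip(effect_imgs, config.effects):
        group_imgs[s.group] = group_imgs[s.group] + img
    ref_group = "HC" if spec.group != "HC" else "PD-NFOG"

    def _proc(arr):
        v = Volume(data=arr, affine=np.diag([*config.voxel_size_mm, 1.0]), mask=mask_vol.mask)
        return gaussian_smooth(normalize_global_mean(v, 1.0), fwhm_mm).data

    delta = float(np.abs(_proc(group_imgs[spec.group])[region] - _proc(group_imgs[ref_group])[region]).mean())
    kappa = smoothing_noise_factor(config.grid_shape, config.voxel_size_mm, fwhm_mm)
    gmean = float(baseline[mask_vol.mask].mean())
    return delta * gmean / (target_d * kappa)


def fogq_weight_for_partial_r(sigma_x: float, sigma_eps: float, target_r: float) -> float:
    """Weight w so that y = w*x + eps has corr(x, y) = target_r when x and eps
    are independent with the given SDs (the generative partial correlation once
    covariate contributions, orthogonal to x, are added to y)."""
    if not (-1.0 < target_r < 1.0):
        raise ConfigurationError("target_r must be in (-1, 1)")
    return target_r / np.sqrt(1.0 - target_r**2) * sigma_eps / sigma_x


# ---------------------------------------------------------------------------
# Direct low-dimensional simulators for the partial-correlation stage
# ---------------------------------------------------------------------------

def simulate_partial_corr_draw(n: int, partial_r: float, seed: int):
    """One draw (x, y, C) with exact population partial corr(x, y | C) = partial_r.

    Both x and y load on the two covariates in C (severity-like confounding);
    their residual parts are bivariate normal with correlation ``partial_r``,
    which is by construction the population partial correlation.
    """
    rng = np.random.default_rng(seed)
    C = rng.normal(size=(n, 2))
    u = rng.normal(size=n)
    v = partial_r * u + np.sqrt(1.0 - partial_r**2) * rng.normal(size=n)
    x = 0.5 * C[:, 0] - 0.3 * C[:, 1] + u
    y = 0.8 * C[:, 0] + 0.4 * C[:, 1] + v
    return x, y, C


def simulate_confounded_draw(n: int, seed: int):
    """One draw where x and y are associated *only* through the covariate:
    population partial corr(x, y | C) = 0."""
    rng = np.random.default_rng(seed)
    c = rng.normal(size=n)
    C = np.c_[c, rng.normal(size=n)]
    x = c + rng.normal(size=n)
    y = 2.0 * c + rng.normal(size=n)
    return x, y, C


def default_cohort_config(seed: int = 0) -> CohortConfig:
    """The reference synthetic cohort: 17 HC / 11 PD-NFOG / 18 PD-FOG on a
    32-voxel grid with 4-mm voxels, one shared PD hypometabolic region and
    FOG-specific hyper- and hypometabolic regions."""
    effects = [
        EffectSpec(region_center=(16, 13, 14), region_radius=3, group="PD-NFOG", effect_fraction=-0.15),
        EffectSpec(region_center=(20, 19, 19), region_radius=3, group="PD-FOG", effect_fraction=0.15),
        EffectSpec(region_center=(16, 13, 14), region_radius=3, group="PD-FOG", effect_fraction=-0.15),
        EffectSpec(region_center=(12, 22, 13), region_radius=3, group="PD-FOG", effect_fraction=-0.12),
    ]
    return CohortConfig(effects=effects, fogq=FogqModel(roi_weights={1: 30.0}), seed=seed)
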