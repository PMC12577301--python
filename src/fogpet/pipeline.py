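"""End-to-end orchestration: simulate -> preprocess -> voxel stats -> ROI
partial correlation -> cross-validated evaluation, with a provenance manifest.

Each stage draws its randomness from a seed fanned out of the single run seed
through ``numpy.random.SeedSequence(seed).spawn``, so stages are individually
reproducible; deterministic stages are bit-identical across reruns of the
same configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .baselines import build_baselines
from .config import RunConfig, save_config
from .cv import run_cv, select_task
from .roi import extract_roi_means, roi_fogq_partial_correlations
from .stats import peak_table, threshold_and_cluster, two_sample_t_map
from .synthetic import generate_cohort, write_cohort
from .volume import Volume, gaussian_smooth, normalize_global_mean, write_volume

__all__ = ["run_all", "preprocess_volumes", "stage_seeds", "PipelineError"]

log = logging.getLogger("fogpet")

STAGES = ("simulate", "preprocess", "voxelstats", "roicorr", "evaluate")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage. Partial outputs are kept."""


def stage_seeds(seed: int) -> dict[str, int]:
    """Deterministic per-stage seeds (< 2^31) fanned out from the run seed."""
    children = np.random.SeedSequence(seed).spawn(len(STAGES))
    return {name: int(c.generate_state(1)[0] % (2**31 - 1)) for name, c in zip(STAGES, children)}


def preprocess_volumes(volumes, fwhm_mm: float = 10.0, target: float = 1.0) -> list[Volume]:
    """Global-mean normalization (to ``target``) followed by Gaussian smoothing."""
    return [gaussian_smooth(normalize_global_mean(v, target), fwhm_mm) for v in volumes]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_all(config: RunConfig, output_dir=None) -> Path:
    """Execute the full pipeline; returns the run directory.

    Writes per-stage outputs (NIfTI volumes and maps, TSV tables, JSON
    reports) plus ``manifest.json`` tracing every output file to the config
    hash and seed.
    """
    outdir = Path(output_dir if output_dir is not None else config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.seed)
    cfg_path = save_config(config, outdir / "config.yaml")
    cfg_hash = hashlib.sha256(cfg_path.read_bytes()).hexdigest()
    manifest: dict = {
        "fogpet_version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "stage_seeds": seeds,
        "config_sha256": cfg_hash,
        "stages": {},
    }

    def _record(stage: str, files: list[Path]) -> None:
        manifest["stages"][stage] = {
            str(f.relative_to(outdir)): _sha256(f) for f in files if f.is_file()
        }
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1)

    # ---- simulate ---------------------------------------------------------
    try:
        cohort_cfg = config.cohort.model_copy(update={"seed": seeds["simulate"]})
        records, volumes, truth = generate_cohort(cohort_cfg)
        cohort_dir = write_cohort(records, volumes, truth, outdir / "cohort")
        log.info("simulate: %d subjects", len(records))
        _record("simulate", sorted(cohort_dir.iterdir()))
    except Exception as exc:
        raise PipelineError(f"stage 'simulate' failed: {exc}") from exc

    # ---- preprocess -------------------------------------------------------
    try:
        processed = preprocess_volumes(volumes, config.preprocess.fwhm_mm, config.preprocess.target)
        pre_dir = outdir / "preprocessed"
        pre_dir.mkdir(exist_ok=True)
        for rec, vol in zip(records, processed):
            write_volume(vol, pre_dir / f"{rec.id}.nii.gz")
        log.info("preprocess: fwhm=%.1f mm, target=%.2f", config.preprocess.fwhm_mm,
                 config.preprocess.target)
        _record("preprocess", sorted(pre_dir.iterdir()))
    except Exception as exc:
        raise PipelineError(f"stage 'preprocess' failed: {exc}") from exc

    # ---- voxel statistics (PD-FOG vs PD-NFOG) -----------------------------
    try:
        fog = [v for r, v in zip(records, processed) if r.group == "PD-FOG"]
        nfog = [v for r, v in zip(records, processed) if r.group == "PD-NFOG"]
        mask = volumes[0].mask
        stat = two_sample_t_map(fog, nfog, mask)
        stats_dir = outdir / "voxelstats"
        stats_dir.mkdir(exist_ok=True)
        write_volume(Volume(stat.z, stat.affine), stats_dir / "zmap_fog_gt_nfog.nii.gz")
        tables = []
        cluster_sets = {}
        for direction in ("A_gt_B", "A_lt_B"):
            cs = threshold_and_cluster(stat, config.stats.p_voxel, config.stats.extent_k,
                                       config.stats.connectivity, direction)
            cluster_sets[direction] = cs
            tables.append(peak_table(cs))
        peaks = pd.concat(tables, ignore_index=True)
        peaks.to_csv(stats_dir / "clusters.tsv", sep="\t", index=False)
        log.info("voxelstats: %d clusters", len(peaks))
        _record("voxelstats", sorted(stats_dir.iterdir()))
    except Exception as exc:
        raise PipelineError(f"stage 'voxelstats' failed: {exc}") from exc

    # ---- ROI partial correlation ------------------------------------------
    try:
        roicorr_dir = outdir / "roicorr"
        roicorr_dir.mkdir(exist_ok=True)
        all_clusters = cluster_sets["A_gt_B"].clusters + cluster_sets["A_lt_B"].clusters
        pd_idx = [i for i, r in enumerate(records) if r.group != "HC"]
        files: list[Path] = []
        if all_clusters:
            cs = cluster_sets["A_gt_B"]
            cs = type(cs)(clusters=all_clusters, affine=cs.affine, z_threshold=cs.z_threshold,
                          extent_k=cs.extent_k, connectivity=cs.connectivity)
            roi_mat = extract_roi_means([processed[i] for i in pd_idx], cs,
                                        subject_ids=[records[i].id for i in pd_idx])
            clin = pd.DataFrame(
                [{"id": records[i].id, "fogq": records[i].fogq, "updrs3": records[i].updrs3,
                  "ledd": records[i].ledd} for i in pd_idx]
            ).set_index("id")
            corr = roi_fogq_partial_correlations(roi_mat, clin,
                                                 covariate_names=config.corr.covariates,
                                                 alpha=config.corr.alpha)
            roi_mat.to_csv(roicorr_dir / "roi_means.tsv", sep="\t")
            corr.to_csv(roicorr_dir / "partial_correlations.tsv", sep="\t", index=False)
            files = sorted(roicorr_dir.iterdir())
            log.info("roicorr: %d ROIs, %d FDR-significant", len(corr), int(corr.rejected.sum()))
        else:
            log.info("roicorr: no clusters survived; stage skipped")
        _record("roicorr", files)
    except Exception as exc:
        raise PipelineError(f"stage 'roicorr' failed: {exc}") from exc

    # ---- evaluation -------------------------------------------------------
    try:
        eval_dir = outdir / "evaluation"
        eval_dir.mkdir(exist_ok=True)
        truth_masks = truth.effect_masks
        files = []
        for task in config.evaluation.tasks:
            idx, y = select_task(records, task)
            task_kind = "regress" if task == "fogq_regress" else "classify"
            vols = [processed[i] for i in idx]
            ids = [records[i].id for i in idx]
            for model_name in config.evaluation.models:
                def factory(fold_seed, _name=model_name):
                    if _name == "cnn3d":
                        return build_baselines("cnn3d", task=task_kind, train_cfg=config.train)
                    if _name == "cnn2d":
                        return build_baselines("cnn2d", train_cfg=config.train)
                    if _name in ("poly_reg", "tree_reg", "forest_reg"):
                        return build_baselines(_name, region_masks=truth_masks)
                    return build_baselines(_name)
                report = run_cv(vols, y, factory, task_kind=task_kind,
                                k=config.evaluation.k, seed=seeds["evaluate"],
                                subject_ids=ids, task_name=task, model_name=model_name)
                out = eval_dir / f"{task}_{model_name}.json"
                out.write_text(report.to_json())
                files.append(out)
                log.info("evaluate: %s/%s done", task, model_name)
        _record("evaluate", files)
    except Exception as exc:
        raise PipelineError(f"stage 'evaluate' failed: {exc}") from exc

    return outdir
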