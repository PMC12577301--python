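"""Voxel-wise two-sample contrasts, Gaussianized Z maps, and cluster-extent
thresholding — the statistical-parametric-mapping stage.

Group maps are pooled-variance two-sample t statistics computed independently
at every in-mask voxel, Gaussianized to Z through the exact t CDF, thresholded
one-sidedly at an uncorrected voxel-level p, and cleaned by discarding
connected suprathreshold components smaller than a cluster-extent threshold
(the classic "p < 0.001 uncorrected, k = 25" regime). Increases and decreases
are handled as two separate one-sided contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats as sps

from .volume import Volume

__all__ = [
    "StatMap",
    "Cluster",
    "ClusterSet",
    "two_sample_t_map",
    "t_to_z",
    "threshold_and_cluster",
    "peak_table",
    "CONNECTIVITY_STRUCTS",
]

DIRECTIONS = ("A_gt_B", "A_lt_B")

#: scipy binary structures for the three standard 3D voxel connectivities
CONNECTIVITY_STRUCTS = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass
class StatMap:
    """Voxel-wise t and Z maps for a two-group contrast (A minus B)."""

    t: np.ndarray
    z: np.ndarray
    df: int
    mask: np.ndarray
    affine: np.ndarray
    n_zero_variance: int = 0

    def __post_init__(self) -> None:
        if self.df < 1:
            raise ValueError(f"df must be >= 1, got {self.df}")


@dataclass
class Cluster:
    """One suprathreshold connected component."""

    voxels: np.ndarray  # (k, 3) int voxel coordinates
    peak_voxel: tuple[int, int, int]
    peak_z: float
    direction: str

    @property
    def size(self) -> int:
        return int(len(self.voxels))

    def mask(self, shape) -> np.ndarray:
        out = np.zeros(shape, dtype=bool)
        out[tuple(self.voxels.T)] = True
        return out


@dataclass
class ClusterSet:
    """Clusters surviving threshold + extent for one or both directions."""

    clusters: list[Cluster] = field(default_factory=list)
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    z_threshold: float = np.nan
    extent_k: int = 0
    connectivity: int = 26

    def __len__(self) -> int:
        return len(self.clusters)

    def __iter__(self):
        return iter(self.clusters)


def two_sample_t_map(group_a, group_b, mask: np.ndarray | None = None) -> StatMap:
    """Pooled-variance two-sample t statistic (A minus B) at every in-mask voxel.

    Voxels whose pooled variance is zero carry no information and are removed
    from the analysis mask (their count is reported on the result), mirroring
    the implicit-masking behavior of standard SPM-style pipelines.
    """

    def _stack(vols):
        arrs, affine = [], None
        for v in vols:
            if isinstance(v, Volume):
                arrs.append(v.data)
                affine = v.affine if affine is None else affine
            else:
                arrs.append(np.asarray(v))
        return np.stack(arrs).astype(np.float64), affine

    A, affine_a = _stack(group_a)
    B, affine_b = _stack(group_b)
    affine = affine_a if affine_a is not None else (affine_b if affine_b is not None else np.eye(4))
    if A.shape[1:] != B.shape[1:]:
        raise ValueError(f"grid mismatch: {A.shape[1:]} vs {B.shape[1:]}")
    n_a, n_b = A.shape[0], B.shape[0]
    if n_a < 2 or n_b < 2:
        raise ValueError(f"need >= 2 subjects per group, got {n_a} and {n_b}")
    if mask is None:
        mask = np.ones(A.shape[1:], dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != A.shape[1:]:
        raise ValueError("mask shape does not match volumes")

    df = n_a + n_b - 2
    mean_a, mean_b = A.mean(axis=0), B.mean(axis=0)
    ss_a = ((A - mean_a) ** 2).sum(axis=0)
    ss_b = ((B - mean_b) ** 2).sum(axis=0)
    pooled_var = (ss_a + ss_b) / df

    zero_var = mask & (pooled_var <= 0)
    eff_mask = mask & ~zero_var
    se = np.sqrt(pooled_var * (1.0 / n_a + 1.0 / n_b))
    t = np.zeros_like(mean_a)
    np.divide(mean_a - mean_b, se, out=t, where=eff_mask)
    t = np.where(eff_mask, t, 0.0)
    z = np.where(eff_mask, t_to_z(t, df), 0.0)
    return StatMap(t=t, z=z, df=df, mask=eff_mask, affine=affine,
                   n_zero_variance=int(zero_var.sum()))


def t_to_z(t, df: int):
    """Gaussianize a Student-t statistic: z = Phi^-1(T_df(t)).

    Computed through tail-symmetric survival functions so that very large |t|
    (up to and beyond 40) maps through far-tail probabilities without
    catastrophic cancellation; extreme values saturate gracefully at +/-inf.
    """
    if df < 1:
        raise ValueError(f"df must be >= 1, got {df}")
    t = np.asarray(t, dtype=np.float64)
    # upper-tail p for |t|, then z = Phi^-1(1 - p) = -Phi^-1(p) via isf
    p_tail = sps.t.sf(np.abs(t), df)
    z_mag = sps.norm.isf(p_tail)
    return np.sign(t) * z_mag if t.ndim else float(np.sign(t) * z_mag)


def threshold_and_cluster(
    stat: StatMap,
    p_voxel: float = 0.001,
    extent_k: int = 25,
    connectivity: int = 26,
    direction: str = "A_gt_B",
) -> ClusterSet:
    """One-sided threshold at ``p_voxel`` and cluster-extent filtering.

    Suprathreshold voxels (Z beyond the one-sided normal quantile, in the
    requested direction) are labeled into connected components under the given
    voxel connectivity; components with fewer than ``extent_k`` voxels are
    discarded. Run once per direction to obtain increases and decreases.
    """
    if not (0.0 < p_voxel < 1.0):
        raise ValueError(f"p_voxel must be in (0,1), got {p_voxel}")
    if extent_k < 1:
        raise ValueError(f"extent_k must be >= 1, got {extent_k}")
    if connectivity not in CONNECTIVITY_STRUCTS:
        raise ValueError(f"connectivity must be one of {sorted(CONNECTIVITY_STRUCTS)}, got {connectivity}")
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be one of {DIRECTIONS}, got {direction!r}")

    z_thr = float(sps.norm.isf(p_voxel))
    signed_z = stat.z if direction == "A_gt_B" else -stat.z
    supra = stat.mask & (signed_z > z_thr)

    labels, n_labels = ndimage.label(supra, structure=CONNECTIVITY_STRUCTS[connectivity])
    clusters: list[Cluster] = []
    for lab in range(1, n_labels + 1):
        vox = np.argwhere(labels == lab)
        if len(vox) < extent_k:
            continue
        zs = signed_z[tuple(vox.T)]
        peak_i = int(np.argmax(zs))
        peak_voxel = tuple(int(c) for c in vox[peak_i])
        peak_z = float(stat.z[peak_voxel])
        clusters.append(Cluster(voxels=vox, peak_voxel=peak_voxel, peak_z=peak_z, direction=direction))
    clusters.sort(key=lambda c: -abs(c.peak_z))
    return ClusterSet(clusters=clusters, affine=stat.affine, z_threshold=z_thr,
                      extent_k=extent_k, connectivity=connectivity)


def peak_table(clusters: ClusterSet, affine: np.ndarray | None = None) -> pd.DataFrame:
    """One row per cluster: direction, size, peak world coordinates (mm), peak Z.

    World coordinates are ``affine @ [i, j, k, 1]``. Rows are sorted by
    descending |peak Z|. An empty cluster set yields a header-only table.
    """
    affine = clusters.affine if affine is None else np.asarray(affine)
    cols = ["direction", "cluster_id", "size", "peak_x_mm", "peak_y_mm", "peak_z_mm", "peak_Z"]
    rows = []
    ordered = sorted(clusters.clusters, key=lambda c: -abs(c.peak_z))
    for cid, cl in enumerate(ordered):
        world = (affine @ np.array([*cl.peak_voxel, 1.0]))[:3]
        rows.append({
            "direction": cl.direction, "cluster_id": cid, "size": cl.size,
            "peak_x_mm": float(world[0]), "peak_y_mm": float(world[1]),
            "peak_z_mm": float(world[2]), "peak_Z": cl.peak_z,
        })
    return pd.DataFrame(rows, columns=cols)
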