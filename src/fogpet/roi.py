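"""ROI mean extraction and partial correlation with FDR control.

Per-subject mean normalized uptake is extracted over each significant
cluster; each ROI's association with FOG-Q severity is then tested as a
partial correlation controlling disease-severity confounders (UPDRS-III and
LEDD), with two-tailed Student-t p-values and Benjamini-Hochberg FDR
correction across ROIs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .stats import ClusterSet
from .volume import Volume

__all__ = [
    "PartialCorrResult",
    "extract_roi_means",
    "partial_correlation",
    "fdr_bh",
    "roi_fogq_partial_correlations",
]


@dataclass
class PartialCorrResult:
    """Partial correlation of one ROI with the outcome, given covariates."""

    roi_id: str
    r: float
    t_stat: float
    df: int
    p_raw: float
    p_fdr: float = np.nan
    rejected: bool = False


def extract_roi_means(volumes, clusters: ClusterSet, subject_ids=None) -> pd.DataFrame:
    """Subjects x ROIs matrix of mean intensity over each cluster's voxels.

    ROI j's column is the arithmetic mean of each subject's volume over
    cluster j's voxel set. Row order follows ``volumes``.
    """
    if len(clusters) == 0:
        raise ValueError("cluster set is empty; no ROIs to extract")
    idx_sets = []
    for j, cl in enumerate(clusters):
        if cl.size == 0:
            raise ValueError(f"cluster {j} is empty")
        idx_sets.append(tuple(cl.voxels.T))
    rows = []
    for vol in volumes:
        data = vol.data if isinstance(vol, Volume) else np.asarray(vol)
        rows.append([float(data[ix].mean()) for ix in idx_sets])
    cols = [f"roi_{j}" for j in range(len(clusters))]
    if subject_ids is None:
        subject_ids = [f"sub-{i:03d}" for i in range(len(rows))]
    return pd.DataFrame(rows, index=list(subject_ids), columns=cols)


def _residualize(v: np.ndarray, design: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(design, v, rcond=None)
    return v - design @ beta


def partial_correlation(x, y, covariates=None) -> PartialCorrResult:
    """Partial Pearson correlation of x and y given covariates.

    Both variables are residualized on [1, covariates] by least squares and
    the residuals are correlated. With k covariates and n samples,
    t = r * sqrt(df / (1 - r^2)) with df = n - 2 - k, and the p-value is
    two-tailed from the Student-t distribution. With k = 0 this reduces to
    the plain Pearson correlation test.
    """
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    n = len(x)
    if len(y) != n:
        raise ValueError("x and y must have equal length")
    if covariates is None:
        C = np.empty((n, 0))
    else:
        C = np.asarray(covariates, dtype=np.float64)
        C = C.reshape(n, -1)
    k = C.shape[1]
    if n <= k + 2:
        raise ValueError(f"need n > k + 2 (n={n}, k={k})")
    design = np.c_[np.ones(n), C]
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("covariate matrix (with intercept) is rank-deficient")
    rx = _residualize(x, design)
    ry = _residualize(y, design)
    sx, sy = rx.std(), ry.std()
    if sx == 0.0 or sy == 0.0:
        raise ValueError("zero residual variance; partial correlation undefined")
    r = float(np.clip((rx * ry).mean() / (sx * sy), -1.0, 1.0))
    df = n - 2 - k
    if abs(r) == 1.0:
        t_stat, p = np.inf * np.sign(r), 0.0
    else:
        t_stat = float(r * np.sqrt(df / (1.0 - r**2)))
        p = float(2.0 * sps.t.sf(abs(t_stat), df))
    return PartialCorrResult(roi_id="", r=r, t_stat=t_stat, df=df, p_raw=p)


def fdr_bh(p_values, alpha: float = 0.05):
    """Benjamini-Hochberg step-up FDR correction.

    Returns (adjusted p-values, rejection flags). Adjusted p-values are the
    standard monotonized min(m * p_(i) / i, 1); a hypothesis is rejected when
    its raw p is at or below the largest p_(i) with p_(i) <= i * alpha / m.
    """
    p = np.asarray(p_values, dtype=np.float64)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, *_ = multipletests(p, alpha=alpha, method="fdr_bh")
    return p_adj, reject


def roi_fogq_partial_correlations(
    roi_matrix: pd.DataFrame,
    clinical: pd.DataFrame,
    outcome: str = "fogq",
    covariate_names=("updrs3", "ledd"),
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-ROI partial correlation with the outcome, FDR-corrected across ROIs.

    ``clinical`` must be indexable by the ROI matrix's subject index and carry
    the outcome and covariate columns. Returns a table with columns
    roi_id, r, t, df, p_raw, p_fdr, rejected.
    """
    clin = clinical.loc[roi_matrix.index]
    y = clin[outcome].to_numpy(dtype=float)
    C = clin[list(covariate_names)].to_numpy(dtype=float)
    results = []
    for roi in roi_matrix.columns:
        res = partial_correlation(roi_matrix[roi].to_numpy(dtype=float), y, C)
        res.roi_id = str(roi)
        results.append(res)
    p_adj, reject = fdr_bh([r.p_raw for r in results], alpha=alpha)
    for res, pa, rj in zip(results, p_adj, reject):
        res.p_fdr, res.rejected = float(pa), bool(rj)
    return pd.DataFrame(
        [{"roi_id": r.roi_id, "r": r.r, "t": r.t_stat, "df": r.df,
          "p_raw": r.p_raw, "p_fdr": r.p_fdr, "rejected": r.rejected}
         for r in results]
    )
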