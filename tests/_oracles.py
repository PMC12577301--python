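"""Independent brute-force oracles used only by the test suite."""

from __future__ import annotations

import itertools

import numpy as np


def flood_fill_label(binary: np.ndarray, connectivity: int) -> list[set]:
    """Connected components of a 3D boolean map by explicit BFS flood fill.

    Neighborhoods: 6 (faces), 18 (faces+edges), 26 (faces+edges+corners).
    Returns a list of voxel-coordinate sets.
    """
    offsets = []
    for off in itertools.product((-1, 0, 1), repeat=3):
        if off == (0, 0, 0):
            continue
        order = sum(o != 0 for o in off)
        if (connectivity == 6 and order == 1) or (connectivity == 18 and order <= 2) or connectivity == 26:
            offsets.append(off)
    remaining = set(map(tuple, np.argwhere(binary)))
    comps = []
    while remaining:
        seed = remaining.pop()
        comp = {seed}
        frontier = [seed]
        while frontier:
            cur = frontier.pop()
            for off in offsets:
                nb = (cur[0] + off[0], cur[1] + off[1], cur[2] + off[2])
                if nb in remaining:
                    remaining.remove(nb)
                    comp.add(nb)
                    frontier.append(nb)
        comps.append(comp)
    return comps


def pairwise_auc(y_true, scores) -> float:
    """AUC as the Mann-Whitney probability, by explicit pair enumeration
    (ties count one half)."""
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    pos = scores[y_true == 1]
    neg = scores[y_true == 0]
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def partial_corr_normal_equations(x, y, C) -> float:
    """Residualize-then-correlate using explicit normal equations."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    D = np.c_[np.ones(len(x)), np.asarray(C, float).reshape(len(x), -1)]
    P = D @ np.linalg.inv(D.T @ D) @ D.T
    rx = x - P @ x
    ry = y - P @ y
    return float(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))


def bh_stepup(p, alpha) -> np.ndarray:
    """Benjamini-Hochberg rejection flags evaluated literally from the rule."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    k = 0
    for i, oi in enumerate(order, start=1):
        if p[oi] <= i * alpha / m:
            k = i
    reject = np.zeros(m, dtype=bool)
    reject[order[:k]] = True
    return reject


def dense_gaussian_kernel_3d(sigma_voxels, half_width) -> np.ndarray:
    """Directly evaluated, normalized 3D Gaussian on an odd grid."""
    ax = np.arange(-half_width, half_width + 1, dtype=float)
    g = [np.exp(-(ax**2) / (2.0 * s**2)) for s in np.broadcast_to(sigma_voxels, (3,))]
    g = [v / v.sum() for v in g]
    return g[0][:, None, None] * g[1][None, :, None] * g[2][None, None, :]
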