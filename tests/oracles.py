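"""Independent brute-force oracles used by the test suite only."""

from itertools import combinations

import numpy as np
from scipy.stats import rankdata
from skimage.morphology import disk


def brute_force_opening(image: np.ndarray, radius: int) -> np.ndarray:
    """Grayscale opening by literal sliding min-then-max over a disk."""
    fp = disk(radius).astype(bool)
    r = radius
    pad = np.pad(np.asarray(image, dtype=float), 2 * r, mode="reflect")
    h, w = pad.shape
    ero = np.full_like(pad, np.inf)
    for i in range(r, h - r):
        for j in range(r, w - r):
            ero[i, j] = pad[i - r : i + r + 1, j - r : j + r + 1][fp].min()
    dil = np.full_like(pad, -np.inf)
    for i in range(2 * r, h - 2 * r):
        for j in range(2 * r, w - 2 * r):
            dil[i, j] = ero[i - r : i + r + 1, j - r : j + r + 1][fp].max()
    return dil[2 * r : -2 * r, 2 * r : -2 * r]


def brute_force_optimal_threshold(image: np.ndarray, mask: np.ndarray) -> float:
    """Exhaustive F1 scan over every unique intensity (ties to smaller tau)."""
    image = np.asarray(image, dtype=float).ravel()
    mask = np.asarray(mask, dtype=bool).ravel()
    best_tau, best_f1 = None, -1.0
    for tau in np.unique(image):
        pred = image > tau
        tp = (pred & mask).sum()
        fp = (pred & ~mask).sum()
        fn = (~pred & mask).sum()
        f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
        if f1 > best_f1:
            best_f1, best_tau = f1, tau
    return float(best_tau)


def brute_force_wilcoxon(x, y):
    """Exact signed-rank two-sided p by literal enumeration of sign patterns."""
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    d = d[d != 0]
    m = len(d)
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = []
    for bits in range(2**m):
        signs = [(bits >> k) & 1 for k in range(m)]
        ws.append(sum(r for r, s in zip(ranks, signs) if s))
    ws = np.asarray(ws)
    p_lo = (ws <= w_obs + 1e-12).mean()
    p_hi = (ws >= w_obs - 1e-12).mean()
    return w_obs, min(1.0, 2.0 * min(p_lo, p_hi))


def brute_force_mann_whitney(x, y):
    """Exact two-sided Mann-Whitney p by enumeration of all labelings."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1 = len(x)
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    base = n1 * (n1 + 1) / 2.0
    u_obs = ranks[:n1].sum() - base
    mu = n1 * len(y) / 2.0
    us = np.asarray(
        [ranks[list(idx)].sum() - base for idx in combinations(range(len(pooled)), n1)]
    )
    return u_obs, float((np.abs(us - mu) >= abs(u_obs - mu) - 1e-12).mean())


def brute_force_linkage_clusters(points: np.ndarray, eps: float) -> list:
    """Single-linkage components by O(n^2) pairwise union-find."""
    n = len(points)
    parent = list(range(n))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i in range(n):
        for j in range(i + 1, n):
            if np.hypot(*(points[i] - points[j])) <= eps:
                parent[find(i)] = find(j)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    return sorted(sorted(g) for g in groups.values())
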