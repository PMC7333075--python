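"""Exhaustive reference implementations used for verification.

These brute-force routines are deliberately independent of the production
code paths: the DTW reference enumerates every monotone warping path, and
the k-medoids reference enumerates every k-subset of candidate medoids.
Both are exponential/combinatorial and only usable on tiny instances —
which is exactly their job: on instances small enough to enumerate, the
fast implementations must agree with them.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np

__all__ = ["dtw_brute_force", "kmedoids_brute_force"]


def dtw_brute_force(a: np.ndarray, b: np.ndarray,
                    normalized: bool = True) -> float:
    """DTW by enumerating all monotone warping paths.

    A path starts at (0, 0), ends at (n-1, m-1) and moves by (1, 0),
    (0, 1) or (1, 1); its cost is the sum of Euclidean frame distances
    along it.  Returns min cost (divided by the length of the shortest
    minimising path when ``normalized``).  Exponential — lengths <= ~6.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.ndim == 1:
        a = a[:, None]
    if b.ndim == 1:
        b = b[:, None]
    if a.shape[1] != b.shape[1]:
        raise ValueError("channel mismatch")
    n, m = a.shape[0], b.shape[0]
    local = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=2)
    best: list[tuple[float, int]] = [(np.inf, 0)]

    def walk(i: int, j: int, cost: float, length: int) -> None:
        cost += local[i, j]
        length += 1
        if i == n - 1 and j == m - 1:
            if (cost, length) < best[0]:
                best[0] = (cost, length)
            return
        if i + 1 < n and j + 1 < m:
            walk(i + 1, j + 1, cost, length)
        if i + 1 < n:
            walk(i + 1, j, cost, length)
        if j + 1 < m:
            walk(i, j + 1, cost, length)

    walk(0, 0, 0.0, 0)
    cost, length = best[0]
    return cost / length if normalized else cost


def kmedoids_brute_force(D: np.ndarray, k: int) -> tuple[tuple[int, ...], float]:
    """Globally optimal medoid k-subset by full enumeration.

    For every k-subset of indices, assign each point to its nearest medoid
    and score the sum of squared dissimilarities; return the best subset
    and its inertia.  C(n, k) subsets — keep n <= ~15, k <= 4.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    best_subset: tuple[int, ...] | None = None
    best_inertia = np.inf
    D2 = D * D
    for subset in combinations(range(n), k):
        idx = np.array(subset)
        inertia = float(D2[:, idx].min(axis=1).sum())
        if inertia < best_inertia:
            best_inertia = inertia
            best_subset = subset
    return best_subset, best_inertia
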