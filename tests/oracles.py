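"""Independent brute-force reference implementations used only by tests.

These stay deliberately naive (exhaustive enumeration, O(n^3) loops) so they
are simple enough to trust and fully independent of the library code paths
they check.
"""

from __future__ import annotations

import numpy as np


def dtw_brute_force(a: np.ndarray, b: np.ndarray, step: str = "symmetric2",
                    normalize: bool = True) -> float:
    """Minimal warping-path cost by exhaustive enumeration (series length <= ~6).

    Paths move from (0, 0) to (n-1, m-1) with steps (1,1), (1,0), (0,1);
    under the weight-2 diagonal step pattern, diagonal moves (and the start
    cell) count the local cost twice.
    """
    a = np.atleast_2d(np.asarray(a, float))
    b = np.atleast_2d(np.asarray(b, float))
    if a.ndim == 2 and a.shape[1] != b.shape[1]:
        raise ValueError("channel mismatch")
    cost = np.array([[np.linalg.norm(a[i] - b[j]) for j in range(len(b))]
                     for i in range(len(a))])
    n, m = cost.shape
    diag = 2.0 if step == "symmetric2" else 1.0
    start = diag

    best = [np.inf]

    def walk(i: int, j: int, acc: float) -> None:
        if acc >= best[0]:
            return
        if i == n - 1 and j == m - 1:
            best[0] = acc
            return
        if i + 1 < n and j + 1 < m:
            walk(i + 1, j + 1, acc + diag * cost[i + 1, j + 1])
        if i + 1 < n:
            walk(i + 1, j, acc + cost[i + 1, j])
        if j + 1 < m:
            walk(i, j + 1, acc + cost[i, j + 1])

    walk(0, 0, start * cost[0, 0])
    total = best[0]
    return total / (n + m) if normalize else total


def upgma_heights(dist: np.ndarray) -> np.ndarray:
    """Merge heights of unweighted average-linkage clustering, naive O(n^3).

    Inter-cluster distance is the arithmetic mean of all cross-pair leaf
    dissimilarities; returns the sorted sequence of n-1 merge heights.
    """
    n = dist.shape[0]
    clusters: list[list[int]] = [[i] for i in range(n)]
    heights = []
    while len(clusters) > 1:
        best = (np.inf, None, None)
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = np.mean([dist[a, b] for a in clusters[i] for b in clusters[j]])
                if d < best[0]:
                    best = (d, i, j)
        d, i, j = best
        heights.append(d)
        merged = clusters[i] + clusters[j]
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [merged]
    return np.array(heights)
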