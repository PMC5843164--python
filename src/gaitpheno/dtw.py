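"""Multivariate dynamic time warping dissimilarity between gait cycles.

The local cost between epoch ``i`` of one cycle and epoch ``j`` of another is
the Euclidean norm of the difference of their channel vectors (by default the
five sagittal channels, all in degrees).  The DTW distance is the minimal
cumulative cost over monotone warping paths with steps (1,1), (1,0), (0,1).

Step pattern (default ``"symmetric2"``): diagonal steps carry weight 2,
off-diagonal steps weight 1, and the starting cell carries weight 2, so a
purely diagonal alignment of two equal-length series yields exactly the mean
per-epoch cost after normalization by n + m.  ``"symmetric1"`` weights every
step (and the start) 1.  Normalization by n + m is on by default so distances
are comparable across pairs; both choices are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from numba import njit
from scipy.spatial.distance import cdist

from .io import SAGITTAL_CHANNELS, GaitCycle


@njit(cache=True)
def _accumulate(cost: np.ndarray, diag_weight: float, start_weight: float) -> float:
    n, m = cost.shape
    D = np.empty((n, m))
    D[0, 0] = start_weight * cost[0, 0]
    for j in range(1, m):
        D[0, j] = D[0, j - 1] + cost[0, j]
    for i in range(1, n):
        D[i, 0] = D[i - 1, 0] + cost[i, 0]
        for j in range(1, m):
            best = D[i - 1, j - 1] + diag_weight * cost[i, j]
            up = D[i - 1, j] + cost[i, j]
            if up < best:
                best = up
            left = D[i, j - 1] + cost[i, j]
            if left < best:
                best = left
            D[i, j] = best
    return D[n - 1, m - 1]


def _local_cost(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.ndim == 1:
        a = a[:, None]
    if b.ndim == 1:
        b = b[:, None]
    if a.shape[1] != b.shape[1]:
        raise ValueError("series must share the channel dimension")
    return cdist(a, b)


def dtw_distance_matrix_pair(a: np.ndarray, b: np.ndarray, *, step: str = "symmetric2",
                             normalize: bool = True) -> float:
    """DTW distance between two (n_epochs, n_channels) arrays."""
    if step == "symmetric2":
        diag, start = 2.0, 2.0
    elif step == "symmetric1":
        diag, start = 1.0, 1.0
    else:
        raise ValueError(f"unknown step pattern {step!r}")
    cost = np.ascontiguousarray(_local_cost(a, b))
    total = _accumulate(cost, diag, start)
    if normalize:
        total /= cost.shape[0] + cost.shape[1]
    return float(total)


def dtw_distance(a: GaitCycle, b: GaitCycle,
                 channels: Sequence[str] = SAGITTAL_CHANNELS, *,
                 step: str = "symmetric2", normalize: bool = True,
                 z_normalize: bool = False) -> float:
    """Multivariate DTW dissimilarity between two gait cycles.

    ``z_normalize`` standardizes each channel of each cycle to zero mean and
    unit variance before alignment (off by default: all channels share the
    degree unit and offsets are themselves clinically meaningful).
    """
    xa, xb = a.stack(channels), b.stack(channels)
    if z_normalize:
        xa = (xa - xa.mean(axis=0)) / xa.std(axis=0)
        xb = (xb - xb.mean(axis=0)) / xb.std(axis=0)
    return dtw_distance_matrix_pair(xa, xb, step=step, normalize=normalize)


@dataclass
class DistanceMatrix:
    """Symmetric, zero-diagonal cycle-by-cycle dissimilarity matrix."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != len(self.ids):
            raise ValueError("distance matrix must be square and match the id list")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(v) != 0) or np.any(v < 0):
            raise ValueError("distance matrix must have a zero diagonal and be non-negative")
        self.values = v

    @property
    def n(self) -> int:
        return len(self.ids)

    def condensed(self) -> np.ndarray:
        from scipy.spatial.distance import squareform
        return squareform(self.values, checks=False)

    def to_csv(self, path: Path) -> None:
        pd.DataFrame(self.values, index=self.ids, columns=self.ids).to_csv(path)

    @classmethod
    def from_csv(cls, path: Path) -> "DistanceMatrix":
        frame = pd.read_csv(path, index_col=0)
        return cls(ids=list(frame.index.astype(str)), values=frame.to_numpy())


def distance_matrix(cycles: Sequence[GaitCycle],
                    channels: Sequence[str] = SAGITTAL_CHANNELS, *,
                    step: str = "symmetric2", normalize: bool = True,
                    z_normalize: bool = False) -> DistanceMatrix:
    """All-pairs DTW dissimilarities (each pair computed once; symmetry exact)."""
    if len(cycles) < 2:
        raise ValueError("need at least 2 cycles")
    stacks = []
    for c in cycles:
        x = c.stack(channels)
        if z_normalize:
            x = (x - x.mean(axis=0)) / x.std(axis=0)
        stacks.append(x)
    n = len(cycles)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = dtw_distance_matrix_pair(stacks[i], stacks[j], step=step, normalize=normalize)
            out[i, j] = out[j, i] = d
    return DistanceMatrix(ids=[c.cycle_id for c in cycles], values=out)
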