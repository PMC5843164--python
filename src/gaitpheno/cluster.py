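"""Hierarchical clustering of gait cycles into sagittal patterns.

Unweighted average linkage (UPGMA on dissimilarities) builds the dendrogram;
cutting it into ``k`` flat clusters defines the patterns.  The published
analysis chose the number of groups by visual inspection of the dendrogram;
here the cut is an explicit parameter (default ``k = 7``: six multi-cycle
patterns plus one singleton outlier).  Pattern labels are renumbered by
decreasing cluster size (pattern 1 = largest), with the cluster's internal
merge height breaking size ties; singleton clusters are flagged as outliers.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .io import GaitCycle
from .dtw import DistanceMatrix


@dataclass
class Dendrogram:
    """Average-linkage merge tree over a set of cycles."""

    leaf_ids: list[str]
    linkage: np.ndarray  # scipy (n-1, 4) linkage matrix

    def __post_init__(self) -> None:
        Z = np.asarray(self.linkage, dtype=float)
        n = len(self.leaf_ids)
        if Z.shape != (n - 1, 4):
            raise ValueError(f"linkage must have shape ({n - 1}, 4)")
        heights = Z[:, 2]
        if np.any(np.diff(heights) < -1e-12):
            raise ValueError("merge heights must be non-decreasing (no inversions)")
        self.linkage = Z

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def to_newick(self) -> str:
        """Newick string with merge heights encoded as branch lengths."""
        tree = hierarchy.to_tree(self.linkage)

        def node_height(node):
            return 0.0 if node.is_leaf() else node.dist

        def render(node, parent_height):
            length = parent_height - node_height(node)
            if node.is_leaf():
                return f"{self.leaf_ids[node.id]}:{length:.10g}"
            left = render(node.left, node.dist)
            right = render(node.right, node.dist)
            return f"({left},{right}):{length:.10g}"

        return f"({render(tree.left, tree.dist)},{render(tree.right, tree.dist)});"


def average_linkage(dm: DistanceMatrix) -> Dendrogram:
    """UPGMA dendrogram: inter-cluster distance = mean cross-pair dissimilarity."""
    if dm.n < 2:
        raise ValueError("need at least 2 cycles to cluster")
    Z = hierarchy.linkage(dm.condensed(), method="average")
    return Dendrogram(leaf_ids=list(dm.ids), linkage=Z)


@dataclass
class PatternAssignment:
    """cycle_id -> pattern label (1..k); singletons flagged as outliers."""

    table: pd.DataFrame  # columns: cycle_id, pattern, outlier

    def __post_init__(self) -> None:
        required = {"cycle_id", "pattern", "outlier"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"assignment table needs columns {sorted(required)}")

    @property
    def labels(self) -> pd.Series:
        return self.table.set_index("cycle_id")["pattern"]

    def cluster_sizes(self) -> pd.Series:
        return self.table["pattern"].value_counts().sort_index()

    def non_outlier_ids(self) -> list[str]:
        return list(self.table.loc[~self.table["outlier"], "cycle_id"])

    def to_csv(self, path: Path) -> None:
        self.table.to_csv(path, index=False)


def _cluster_merge_heights(Z: np.ndarray, flat: np.ndarray) -> dict[int, float]:
    """Maximum internal merge height of each flat cluster (0 for singletons)."""
    n = len(flat)
    # member leaves of each internal node
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    heights = {lab: 0.0 for lab in np.unique(flat)}
    for i, (a, b, h, _) in enumerate(Z):
        node = n + i
        leaves = members[int(a)] + members[int(b)]
        members[node] = leaves
        labs = {flat[l] for l in leaves}
        if len(labs) == 1:
            lab = labs.pop()
            heights[lab] = max(heights[lab], float(h))
    return heights


def cut_dendrogram(dg: Dendrogram, k: int) -> PatternAssignment:
    """Flat k-cluster cut (undo the last k-1 merges) with size-ranked labels."""
    n = len(dg.leaf_ids)
    if not (1 <= k <= n):
        raise ValueError(f"k must be in [1, {n}], got {k}")
    flat = hierarchy.cut_tree(dg.linkage, n_clusters=k).ravel()
    sizes = pd.Series(flat).value_counts()
    heights = _cluster_merge_heights(dg.linkage, flat)
    min_leaf = {lab: int(np.min(np.flatnonzero(flat == lab))) for lab in sizes.index}
    order = sorted(sizes.index, key=lambda lab: (-sizes[lab], heights[lab], min_leaf[lab]))
    relabel = {old: new + 1 for new, old in enumerate(order)}
    patterns = np.array([relabel[lab] for lab in flat])
    outlier = np.array([sizes[lab] == 1 for lab in flat])
    table = pd.DataFrame({
        "cycle_id": dg.leaf_ids,
        "pattern": patterns,
        "outlier": outlier,
    })
    return PatternAssignment(table=table)


USAGE_CLASSES = ("single pattern", "different pattern per limb", "two patterns in one limb")


def _subject_usage_class(sub: pd.DataFrame) -> str:
    """Usage class of one subject given its (side, pattern) rows."""
    per_side = sub.groupby("side")["pattern"].agg(lambda s: set(s))
    if any(len(pats) > 1 for pats in per_side):
        return "two patterns in one limb"
    all_patterns = set(sub["pattern"])
    if len(all_patterns) > 1:
        return "different pattern per limb"
    return "single pattern"


def pattern_summary(assignment: PatternAssignment,
                    cycles: Sequence[GaitCycle]) -> dict[str, pd.DataFrame]:
    """Cluster sizes/fractions and per-subject pattern-usage classes.

    Outlier cycles are excluded from the usage classification (they do not
    define a pattern a subject "walks with").
    """
    meta = pd.DataFrame({
        "cycle_id": [c.cycle_id for c in cycles],
        "subject_id": [c.subject_id for c in cycles],
        "side": [c.side for c in cycles],
    })
    table = assignment.table.merge(meta, on="cycle_id", validate="one_to_one")
    sizes = table["pattern"].value_counts().sort_index()
    clusters = pd.DataFrame({
        "pattern": sizes.index,
        "n_cycles": sizes.to_numpy(),
        "fraction": sizes.to_numpy() / len(table),
        "outlier": [bool(table.loc[table["pattern"] == p, "outlier"].all()) for p in sizes.index],
    })
    usable = table[~table["outlier"]]
    usage = (
        usable.groupby("subject_id")[["side", "pattern"]]
        .apply(_subject_usage_class)
        .rename("usage_class")
        .reset_index()
    )
    usage_counts = (
        usage["usage_class"].value_counts()
        .reindex(USAGE_CLASSES, fill_value=0)
        .rename_axis("usage_class")
        .reset_index(name="n_subjects")
    )
    usage_counts["fraction"] = usage_counts["n_subjects"] / len(usage)
    return {"clusters": clusters, "subject_usage": usage, "usage_counts": usage_counts,
            "assignment": table}
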