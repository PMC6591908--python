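"""Agglomerative clustering with silhouette-based selection of k.

Metabolites are merged by average linkage (UPGMA-style: the pair of clusters
with the smallest mean inter-cluster dissimilarity merges first, ties broken
lexicographically on cluster indices for cross-platform determinism).  The
number of clusters is chosen to maximize the average silhouette width

    s(i) = (b(i) - a(i)) / max{a(i), b(i)}

where a(i) is the mean distance of item i to its co-members and b(i) the
smallest mean distance to any other cluster; members of singleton clusters
get s(i) = 0 by the standard convention.  The search range defaults to
k in [2, n-1], the values for which the silhouette is defined.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .chemstruct import DistanceMatrix
from .io import DatasetError


@dataclass(frozen=True)
class LinkageTree:
    """Merge history of an agglomerative clustering.

    ``merges`` lists (i, j, height, size): clusters i and j (leaves are
    0..n-1, merged clusters are numbered n, n+1, ... in merge order) joined
    at the given average dissimilarity into a cluster of the given size.
    """

    n_leaves: int
    merges: tuple[tuple[int, int, float, int], ...]

    def heights(self) -> np.ndarray:
        return np.asarray([m[2] for m in self.merges])

    def to_newick(self, ids: Sequence[str]) -> str:
        """Newick string with branch lengths derived from merge heights."""
        if len(ids) != self.n_leaves:
            raise DatasetError("id list length does not match number of leaves")
        label = {i: str(ids[i]) for i in range(self.n_leaves)}
        height = {i: 0.0 for i in range(self.n_leaves)}
        for step, (i, j, h, _) in enumerate(self.merges):
            node = self.n_leaves + step
            bi = max(h - height[i], 0.0)
            bj = max(h - height[j], 0.0)
            label[node] = f"({label[i]}:{bi:.6g},{label[j]}:{bj:.6g})"
            height[node] = h
        root = self.n_leaves + len(self.merges) - 1 if self.merges else 0
        return label[root] + ";"


def average_linkage_tree(dm: DistanceMatrix) -> LinkageTree:
    """UPGMA-style agglomeration of a distance matrix.

    Inter-cluster dissimilarity is the unweighted mean over all member
    pairs, maintained exactly by the Lance-Williams average-linkage update.
    Ties are broken by the lowest (i, j) cluster-index pair.
    """
    n = len(dm.ids)
    if n < 2:
        raise DatasetError("clustering requires at least 2 items")
    # dist maps frozen pairs of active cluster ids to average dissimilarity
    dist: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = float(dm.d[i, j])
    size = {i: 1 for i in range(n)}
    active = set(range(n))
    merges: list[tuple[int, int, float, int]] = []
    next_id = n
    while len(active) > 1:
        best = min(dist.items(), key=lambda kv: (kv[1], kv[0]))
        (i, j), h = best
        si, sj = size[i], size[j]
        new = next_id
        next_id += 1
        for k in active - {i, j}:
            dik = dist.pop((min(i, k), max(i, k)))
            djk = dist.pop((min(j, k), max(j, k)))
            dist[(min(new, k), max(new, k))] = (si * dik + sj * djk) / (si + sj)
        del dist[(i, j)]
        active -= {i, j}
        active.add(new)
        size[new] = si + sj
        merges.append((i, j, h, si + sj))
    return LinkageTree(n_leaves=n, merges=tuple(merges))


def cut_tree(tree: LinkageTree, k: int) -> np.ndarray:
    """Labels from cutting the tree to k clusters.

    Labels are consecutive integers starting at 0, numbered by first
    appearance in leaf order.
    """
    n = tree.n_leaves
    if not 1 <= k <= n:
        raise DatasetError(f"k must lie in [1, {n}], got {k}")
    parent = list(range(n + len(tree.merges)))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for step in range(n - k):
        i, j, _, _ = tree.merges[step]
        node = n + step
        parent[find(i)] = node
        parent[find(j)] = node
    roots = [find(i) for i in range(n)]
    seen: dict[int, int] = {}
    labels = np.empty(n, int)
    for i, r in enumerate(roots):
        if r not in seen:
            seen[r] = len(seen)
        labels[i] = seen[r]
    return labels


def silhouette(dm: DistanceMatrix, labels: Sequence[int]) -> tuple[np.ndarray, float]:
    """Per-item silhouettes s(i) and their mean (the ASW).

    Items in singleton clusters get s(i) = 0.
    """
    labels = np.asarray(labels)
    n = len(dm.ids)
    if labels.shape[0] != n:
        raise DatasetError("label vector length does not match distance matrix")
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise DatasetError("silhouette requires at least 2 clusters")
    if n < 3:
        raise DatasetError("silhouette requires at least 3 items")
    s = np.zeros(n)
    for i in range(n):
        own = labels[i]
        mask_own = (labels == own)
        n_own = int(mask_own.sum())
        if n_own == 1:
            s[i] = 0.0
            continue
        a = dm.d[i, mask_own].sum() / (n_own - 1)
        b = min(dm.d[i, labels == other].mean() for other in uniq if other != own)
        s[i] = 0.0 if max(a, b) == 0.0 else (b - a) / max(a, b)
    return s, float(s.mean())


@dataclass
class ClusterAssignment:
    """A flat clustering of metabolites with its silhouette diagnostics."""

    ids: list[str]
    labels: np.ndarray
    k: int
    asw: float
    silhouettes: np.ndarray
    linkage_tree: LinkageTree | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, int)
        self.silhouettes = np.asarray(self.silhouettes, float)
        if len({*self.labels.tolist()}) != self.k:
            raise DatasetError("labels must take exactly k distinct values")

    def members(self, label: int) -> list[str]:
        return [m for m, l in zip(self.ids, self.labels) if l == label]

    def multi_member_clusters(self) -> dict[int, list[str]]:
        """Clusters of size >= 2: the candidate multi-metabolite bins."""
        out: dict[int, list[str]] = {}
        for lab in sorted(set(self.labels.tolist())):
            mem = self.members(lab)
            if len(mem) >= 2:
                out[lab] = mem
        return out

    def label_map(self) -> dict[str, int]:
        return dict(zip(self.ids, self.labels.tolist()))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"cluster": self.labels, "silhouette": self.silhouettes},
            index=pd.Index(self.ids, name="metabolite_id"),
        )


def select_k(
    dm: DistanceMatrix, k_range: tuple[int, int] | None = None
) -> ClusterAssignment:
    """Cut the average-linkage tree at every k in range; keep the highest ASW.

    The range defaults to [2, n-1]; ties are broken toward the smallest k.
    """
    n = len(dm.ids)
    if n < 3:
        raise DatasetError("select_k requires at least 3 items")
    k_lo, k_hi = k_range if k_range is not None else (2, n - 1)
    if not 2 <= k_lo <= k_hi <= n - 1:
        raise DatasetError(f"k_range must satisfy 2 <= lo <= hi <= {n - 1}")
    tree = average_linkage_tree(dm)
    best: ClusterAssignment | None = None
    for k in range(k_lo, k_hi + 1):
        labels = cut_tree(tree, k)
        sil, asw = silhouette(dm, labels)
        if best is None or asw > best.asw:
            best = ClusterAssignment(
                ids=list(dm.ids), labels=labels, k=k, asw=asw,
                silhouettes=sil, linkage_tree=tree,
            )
    assert best is not None
    return best


def cluster_significant(
    dm: DistanceMatrix, k_range: tuple[int, int] | None = None
) -> ClusterAssignment:
    """Cluster the significant-metabolite distance matrix as the full panel.

    With fewer than 3 metabolites the silhouette criterion is undefined and
    an all-singleton assignment is returned with a warning.  Likewise, when
    the best achievable ASW is not positive the items carry no
    better-than-chance group structure (e.g. mutually equidistant
    metabolites), and all singletons are returned rather than arbitrary
    bins.
    """
    n = len(dm.ids)
    def _singletons(reason: str) -> ClusterAssignment:
        warnings.warn(f"{reason}; returning singleton clusters")
        return ClusterAssignment(
            ids=list(dm.ids), labels=np.arange(n), k=n, asw=0.0,
            silhouettes=np.zeros(n), linkage_tree=None,
        )

    if n < 3:
        return _singletons(f"only {n} significant metabolite(s)")
    best = select_k(dm, k_range)
    if best.asw <= 0.0:
        return _singletons(f"no positive-ASW partition (best {best.asw:.3f})")
    return best
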