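"""Two-way agglomerative clustering of conservation profiles.

Complete linkage on Euclidean distances, applied independently to the rows
(genes) and columns (organisms) of the similarity matrix.  The
agglomeration is written out longhand (Lance-Williams max-update) rather
than delegated to a library routine because the merge order under ties is
part of this package's reproducibility contract: the pair with the
smallest original indices always merges first.  Complete linkage is
monotone, so merge heights never decrease — asserted on every run.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from orthoprofiler.similarity_map import SimilarityMatrix

__all__ = [
    "DistanceMatrix",
    "Dendrogram",
    "ClusterAssignment",
    "euclidean_distances",
    "complete_linkage",
    "cut_tree",
    "leaf_order",
    "to_newick",
]


@dataclass(frozen=True)
class DistanceMatrix:
    labels: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self):
        d = np.asarray(self.d, dtype=float)
        if d.shape != (len(self.labels), len(self.labels)):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(d, d.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(d) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(d < 0):
            raise ValueError("distances must be non-negative")
        object.__setattr__(self, "d", d)


@dataclass(frozen=True)
class Dendrogram:
    """Binary merge tree.

    ``merges[k] = (left, right, height, size)`` merges nodes ``left`` and
    ``right`` into new node ``n_leaves + k``; nodes ``0..n_leaves-1`` are
    leaves in input order.
    """

    leaf_labels: tuple[str, ...]
    merges: tuple[tuple[int, int, float, int], ...]

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_labels)

    def __post_init__(self):
        n = self.n_leaves
        if len(self.merges) != n - 1:
            raise ValueError(f"expected {n - 1} merges for {n} leaves, got {len(self.merges)}")
        heights = [h for _, _, h, _ in self.merges]
        if any(b < a - 1e-9 for a, b in zip(heights, heights[1:])):
            raise ValueError("merge heights must be non-decreasing")
        seen: set[int] = set()
        for k, (left, right, _, size) in enumerate(self.merges):
            for child in (left, right):
                if child in seen or not 0 <= child < n + k:
                    raise ValueError("invalid merge structure")
                seen.add(child)


@dataclass(frozen=True)
class ClusterAssignment:
    """Partition of the leaves obtained by cutting a dendrogram into k."""

    assignment: dict[str, int]
    k: int


def euclidean_distances(sim: SimilarityMatrix | np.ndarray,
                        axis: Literal["rows", "columns"] = "rows",
                        labels: Sequence[str] | None = None) -> DistanceMatrix:
    """Pairwise Euclidean distances between row or column profiles.

    Zero-filled absences enter as zeros, exactly as they stand in the
    heatmap's data matrix.
    """
    if isinstance(sim, SimilarityMatrix):
        frame = sim.values if axis == "rows" else sim.values.T
        labels = tuple(frame.index)
        data = frame.to_numpy(dtype=float)
    else:
        data = np.asarray(sim, dtype=float)
        if axis == "columns":
            data = data.T
        labels = tuple(labels) if labels is not None else tuple(str(i) for i in range(len(data)))
    if data.shape[0] < 2:
        raise ValueError(f"need at least 2 items on axis {axis!r}, got {data.shape[0]}")
    d = cdist(data, data, metric="euclidean")
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0  # enforce exact symmetry
    return DistanceMatrix(labels=labels, d=d)


def complete_linkage(dist: DistanceMatrix) -> Dendrogram:
    """Agglomerate with the maximum (complete) linkage rule.

    At each step the pair of active clusters at minimal inter-cluster
    distance merges; the distance between clusters is the maximum pairwise
    distance between their leaves, maintained incrementally via
    ``d(i+j, k) = max(d(i,k), d(j,k))``.  Ties are broken toward the pair
    whose clusters contain the smallest original leaf indices, so results
    are reproducible and identical items agglomerate in input order.
    """
    n = len(dist.labels)
    if n < 2:
        raise ValueError("need at least 2 items to cluster")
    # working distance matrix over all (eventual) nodes
    d = np.full((2 * n - 1, 2 * n - 1), np.inf)
    d[:n, :n] = dist.d
    active = list(range(n))
    sizes = {i: 1 for i in range(n)}
    min_leaf = {i: i for i in range(n)}
    merges: list[tuple[int, int, float, int]] = []
    for step in range(n - 1):
        best_key = (np.inf, n, n)
        best = (np.inf, None, None)
        for ai in range(len(active)):
            i = active[ai]
            row = d[i]
            for aj in range(ai + 1, len(active)):
                j = active[aj]
                lo, hi = sorted((min_leaf[i], min_leaf[j]))
                key = (row[j], lo, hi)
                if key < best_key:
                    best_key = key
                    best = (row[j], i, j)
        h, i, j = best
        new = n + step
        for k in active:
            if k not in (i, j):
                d[new, k] = d[k, new] = max(d[i, k], d[j, k])
        active.remove(i)
        active.remove(j)
        active.append(new)
        min_leaf[new] = min(min_leaf[i], min_leaf[j])
        sizes[new] = sizes[i] + sizes[j]
        merges.append((i, j, float(h), sizes[new]))
    return Dendrogram(leaf_labels=dist.labels, merges=tuple(merges))


def cut_tree(dendrogram: Dendrogram, k: int) -> ClusterAssignment:
    """Cut into exactly ``k`` clusters by undoing the k-1 highest merges.

    Cluster indices are assigned in leaf input order (the cluster holding
    the lowest-index leaf is 0, and so on).
    """
    n = dendrogram.n_leaves
    if not 1 <= k <= n:
        raise ValueError(f"k must lie in [1, {n}], got {k}")
    parent = list(range(2 * n - 1))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for step in range(n - k):
        left, right, _, _ = dendrogram.merges[step]
        new = n + step
        parent[find(left)] = new
        parent[find(right)] = new
    roots: dict[int, int] = {}
    assignment: dict[str, int] = {}
    for leaf in range(n):
        root = find(leaf)
        if root not in roots:
            roots[root] = len(roots)
        assignment[dendrogram.leaf_labels[leaf]] = roots[root]
    return ClusterAssignment(assignment=assignment, k=k)


def _children(dendrogram: Dendrogram) -> dict[int, tuple[int, int]]:
    n = dendrogram.n_leaves
    return {n + k: (left, right) for k, (left, right, _, _) in enumerate(dendrogram.merges)}


def _min_leaf(node: int, children: dict[int, tuple[int, int]], cache: dict[int, int]) -> int:
    if node in cache:
        return cache[node]
    if node not in children:
        cache[node] = node
    else:
        l, r = children[node]
        cache[node] = min(_min_leaf(l, children, cache), _min_leaf(r, children, cache))
    return cache[node]


def leaf_order(dendrogram: Dendrogram) -> list[int]:
    """Leaf permutation from an in-order traversal; at every internal node
    the subtree containing the smallest original leaf index is visited
    first, so identical inputs keep their original order."""
    children = _children(dendrogram)
    cache: dict[int, int] = {}
    root = dendrogram.n_leaves + len(dendrogram.merges) - 1
    order: list[int] = []
    stack = [root]
    while stack:
        node = stack.pop()
        if node not in children:
            order.append(node)
            continue
        l, r = children[node]
        if _min_leaf(l, children, cache) > _min_leaf(r, children, cache):
            l, r = r, l
        stack.append(r)
        stack.append(l)
    return order


def to_newick(dendrogram: Dendrogram) -> str:
    """Serialise as Newick with branch lengths.

    A node's branch length is its parent's merge height minus its own
    (leaves have height 0, so a leaf's branch length is its parent's
    height).  Labels containing Newick metacharacters are quoted.
    """
    children = _children(dendrogram)
    n = dendrogram.n_leaves
    height = {i: 0.0 for i in range(n)}
    for k, (_, _, h, _) in enumerate(dendrogram.merges):
        height[n + k] = h
    meta = set("();:,'\" \t")

    def label(leaf: int) -> str:
        name = dendrogram.leaf_labels[leaf]
        if any(c in meta for c in name):
            return "'" + name.replace("'", "''") + "'"
        return name

    cache: dict[int, int] = {}

    def render(node: int, parent_height: float | None) -> str:
        if node in children:
            l, r = children[node]
            if _min_leaf(l, children, cache) > _min_leaf(r, children, cache):
                l, r = r, l
            body = f"({render(l, height[node])},{render(r, height[node])})"
        else:
            body = label(node)
        if parent_height is None:
            return body
        return f"{body}:{parent_height - height[node]:.12g}"

    root = n + len(dendrogram.merges) - 1
    return render(root, None) + ";"
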