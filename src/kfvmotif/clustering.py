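"""UPGMA motif trees, display transform, and optimal cluster number.

Motif trees are built by average-linkage (UPGMA) clustering of the
pairwise distance matrix.  Because interesting motif distances are often
tiny, distances can first be passed through the exponential transform
D = 1 - exp(-alpha * d) (alpha = 10 by default) which spreads out the
small-distance end of the scale while keeping the ordering.

The number of clusters is chosen by cutting the tree at every level
c = 2 .. n-1 and maximising a log-modified Calinski-Harabasz statistic.
The classic CH index is the variance ratio (SSB/(c-1)) / (SSW/(n-c));
here the sums of squares are generalised to an arbitrary dissimilarity
matrix through the pairwise decomposition of scatter
(sum of deviations from a centroid = pairwise sum / group size):

    W = sum over clusters C of (1/|C|) * sum of d(i,j) for pairs in C
    T = (1/n) * sum of d(i,j) over all pairs,      B = T - W
    CH_log(c) = log( (B/(c-1)) / (W/(n-c)) )

For squared Euclidean input this is exactly the CH index (up to the
final monotone log, which balances the heavy-tailed ratio without
moving the optimum).  Candidate clusterings are horizontal cuts of the
tree only, and the distances scored are the same (possibly transformed)
distances the tree was built on.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from typing import Mapping

import numpy as np

from .distances import DistanceMatrix

DEFAULT_ALPHA = 10.0


def transform_distance(d: float | np.ndarray, alpha: float = DEFAULT_ALPHA):
    """Exponential display transform 1 - exp(-alpha * d).

    Strictly increasing, 0 at d = 0, bounded above by 1.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    arr = np.asarray(d, dtype=float)
    if np.any(arr < 0):
        raise ValueError("distances must be nonnegative")
    out = 1.0 - np.exp(-alpha * arr)
    return float(out) if np.isscalar(d) or arr.ndim == 0 else out


def transform_matrix(dm: DistanceMatrix, alpha: float = DEFAULT_ALPHA) -> DistanceMatrix:
    values = np.asarray(transform_distance(dm.values, alpha))
    np.fill_diagonal(values, 0.0)
    return DistanceMatrix(ids=list(dm.ids), values=values,
                          metric=f"{dm.metric}+exp{alpha:g}", k=dm.k)


@dataclasses.dataclass
class Node:
    """A node of the motif dendrogram (leaf if ``id`` is set)."""

    height: float
    id: str | None = None
    children: tuple["Node", "Node"] | None = None

    @property
    def is_leaf(self) -> bool:
        return self.children is None

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.id]  # type: ignore[list-item]
        left, right = self.children  # type: ignore[misc]
        return left.leaves() + right.leaves()


@dataclasses.dataclass
class UPGMATree:
    """Rooted ultrametric dendrogram with recorded merge order.

    ``merges`` lists (rep_a, rep_b, height) triples in merge order, where
    a cluster's representative is its lexicographically smallest leaf id.
    ``transformed``/``alpha`` record whether the tree was built on
    exponentially transformed distances.
    """

    root: Node
    ids: list[str]
    merges: list[tuple[str, str, float]]
    transformed: bool = False
    alpha: float | None = None

    @property
    def n(self) -> int:
        return len(self.ids)


def upgma(dm: DistanceMatrix, transform: bool = False,
          alpha: float = DEFAULT_ALPHA) -> UPGMATree:
    """Average-linkage clustering of a motif distance matrix.

    Merge heights are half the UPGMA joining distance, so two leaves at
    distance d join at height d/2.  When several pairs tie for the
    minimum distance, the pair whose (representative, representative)
    tuple is lexicographically smallest is merged, which makes the tree
    deterministic.
    """
    if dm.n < 2:
        raise ValueError("UPGMA requires at least 2 motifs")
    values = dm.values
    if transform:
        values = np.asarray(transform_distance(values, alpha))
        np.fill_diagonal(values, 0.0)

    nodes: dict[str, Node] = {i: Node(height=0.0, id=i) for i in dm.ids}
    sizes: dict[str, int] = {i: 1 for i in dm.ids}
    dist: dict[tuple[str, str], float] = {}
    for a in range(dm.n):
        for b in range(a + 1, dm.n):
            key = tuple(sorted((dm.ids[a], dm.ids[b])))
            dist[key] = float(values[a, b])

    merges: list[tuple[str, str, float]] = []
    while len(nodes) > 1:
        (rep_a, rep_b), d = min(dist.items(), key=lambda kv: (kv[1], kv[0]))
        height = d / 2.0
        child_a, child_b = nodes.pop(rep_a), nodes.pop(rep_b)
        merged = Node(height=height, children=(child_a, child_b))
        merges.append((rep_a, rep_b, height))
        size_a, size_b = sizes.pop(rep_a), sizes.pop(rep_b)
        new_rep = rep_a  # keys are sorted, so rep_a < rep_b
        for other in nodes:
            key_a = tuple(sorted((rep_a, other)))
            key_b = tuple(sorted((rep_b, other)))
            d_new = (size_a * dist.pop(key_a) + size_b * dist.pop(key_b)) / (size_a + size_b)
            dist[tuple(sorted((new_rep, other)))] = d_new
        del dist[(rep_a, rep_b)]
        nodes[new_rep] = merged
        sizes[new_rep] = size_a + size_b

    root = next(iter(nodes.values()))
    return UPGMATree(root=root, ids=list(dm.ids), merges=merges,
                     transformed=transform, alpha=alpha if transform else None)


def to_newick(tree: UPGMATree, precision: int = 10) -> str:
    """Serialise a dendrogram to newick with branch lengths."""

    def fmt(x: float) -> str:
        return format(x, f".{precision}g")

    def render(node: Node, parent_height: float) -> str:
        branch = parent_height - node.height
        if node.is_leaf:
            return f"{node.id}:{fmt(branch)}"
        left, right = node.children  # type: ignore[misc]
        inner = f"({render(left, node.height)},{render(right, node.height)})"
        return f"{inner}:{fmt(branch)}"

    root = tree.root
    if root.is_leaf:
        return f"{root.id};"
    left, right = root.children  # type: ignore[misc]
    return f"({render(left, root.height)},{render(right, root.height)});"


def cut_tree(tree: UPGMATree, c: int) -> dict[str, int]:
    """Horizontal cut of the dendrogram into exactly *c* clusters.

    Replays the first n - c merges (UPGMA merge heights are
    non-decreasing, so this is the cut below the (n-c+1)-th merge
    height).  Cluster indices are contiguous from 0 in order of first
    appearance in the input id order.
    """
    n = tree.n
    if not 1 <= c <= n:
        raise ValueError(f"cluster count {c} outside [1, {n}]")
    rep_of: dict[str, str] = {i: i for i in tree.ids}
    members: dict[str, list[str]] = {i: [i] for i in tree.ids}
    for rep_a, rep_b, _height in tree.merges[: n - c]:
        absorbed = members.pop(rep_b)
        members[rep_a].extend(absorbed)
        for leaf in absorbed:
            rep_of[leaf] = rep_a
    cluster_of: dict[str, int] = {}
    assignment: dict[str, int] = {}
    for leaf in tree.ids:
        rep = rep_of[leaf]
        if rep not in cluster_of:
            cluster_of[rep] = len(cluster_of)
        assignment[leaf] = cluster_of[rep]
    return assignment


@dataclasses.dataclass
class ClusterAssignment:
    """A flat clustering of motifs with its CH_log score."""

    c: int
    assignment: dict[str, int]
    ch_log: float


def within_between_scatter(
    dm: DistanceMatrix, assignment: Mapping[str, int]
) -> tuple[float, float]:
    """Size-normalised within (W) and between (B) cluster scatter.

    W sums each cluster's pairwise distances divided by the cluster
    size; B is the total pairwise sum divided by n, minus W.  For
    squared Euclidean distances these equal the within/between sums of
    squares of the classic variance decomposition.
    """
    n = dm.n
    labels = np.array([assignment[i] for i in dm.ids])
    iu = np.triu_indices(n, k=1)
    d = dm.values[iu]
    same = labels[iu[0]] == labels[iu[1]]
    w = 0.0
    for cluster in np.unique(labels):
        in_cluster = same & (labels[iu[0]] == cluster)
        size = int((labels == cluster).sum())
        w += float(d[in_cluster].sum()) / size
    total = float(d.sum()) / n
    return w, total - w


def ch_log(dm: DistanceMatrix, assignment: Mapping[str, int]) -> float:
    """Log-modified Calinski-Harabasz statistic of a flat clustering.

    Returns log((B/(c-1)) / (W/(n-c))) with W and B the size-normalised
    within/between scatter of :func:`within_between_scatter`.  Larger is
    better.  If W is zero (every cluster internally identical) the
    statistic degenerates; +inf is returned with a warning.
    """
    n = dm.n
    c = len({assignment[i] for i in dm.ids})
    if not 2 <= c <= n - 1:
        raise ValueError(f"cluster count {c} outside [2, {n - 1}]")
    w, b = within_between_scatter(dm, assignment)
    if w <= 0:
        warnings.warn("all within-cluster distances are zero; CH_log is degenerate")
        return math.inf
    if b <= 0:
        warnings.warn("no between-cluster scatter; CH_log is degenerate")
        return -math.inf
    return math.log((b / (c - 1)) / (w / (n - c)))


def ch_log_profile(dm: DistanceMatrix, tree: UPGMATree) -> list[tuple[int, float]]:
    """CH_log evaluated at every tree cut c = 2 .. n-1."""
    n = tree.n
    if n < 3:
        raise ValueError("CH_log profile requires at least 3 motifs")
    return [(c, ch_log(dm, cut_tree(tree, c))) for c in range(2, n)]


def optimal_clusters(dm: DistanceMatrix, tree: UPGMATree) -> ClusterAssignment:
    """The tree cut maximising CH_log (smallest c on ties).

    *dm* must be the same geometry the tree was built on: pass the
    transformed matrix if the tree was built on transformed distances.
    """
    profile = ch_log_profile(dm, tree)
    best_c, best_value = max(profile, key=lambda cv: (cv[1], -cv[0]))
    return ClusterAssignment(c=best_c, assignment=cut_tree(tree, best_c),
                             ch_log=best_value)
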