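"""UPGMA dendrograms and cophenetic comparison.

UPGMA (average linkage) repeatedly merges the pair of clusters with the
smallest mean inter-cluster distance; the merge height is that distance, so
the result is a rooted ultrametric tree.  Two dendrograms over the same taxa
are compared by the cophenetic correlation coefficient: the Pearson
correlation between their cophenetic distances (the height at which each leaf
pair is first joined).

The UPGMA here is written in-house so that ties are resolved deterministically
(the pair with the smallest (row, column) index in the current cluster order
is merged first); scipy's average linkage is used as an independent
cross-check in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from .distance import ComparabilityError, DistanceMatrix

__all__ = [
    "Dendrogram",
    "upgma",
    "cophenetic_matrix",
    "cophenetic_correlation",
    "to_newick",
]


@dataclass(frozen=True)
class Dendrogram:
    """Rooted ultrametric merge tree.

    ``merges`` lists ``n - 1`` triples ``(a, b, height)`` in merge order.
    Cluster ids follow the scipy linkage convention: ids ``0..n-1`` are the
    leaves in ``leaves`` order; the cluster created by merge ``i`` has id
    ``n + i``.  Heights are nonnegative and nondecreasing.
    """

    leaves: tuple[str, ...]
    merges: tuple[tuple[int, int, float], ...]

    def __post_init__(self) -> None:
        n = len(self.leaves)
        if n < 2:
            raise ValueError("a dendrogram needs at least two leaves")
        if len(set(self.leaves)) != n:
            raise ValueError("duplicate leaf labels")
        if len(self.merges) != n - 1:
            raise ValueError(f"expected {n - 1} merges, got {len(self.merges)}")
        used: set[int] = set()
        heights = [h for _, _, h in self.merges]
        if any(h < -1e-12 for h in heights):
            raise ValueError("negative merge height")
        if any(b < a - 1e-12 for a, b in zip(heights, heights[1:])):
            raise ValueError("merge heights must be nondecreasing")
        for i, (a, b, _) in enumerate(self.merges):
            for cid in (a, b):
                if not 0 <= cid < n + i:
                    raise ValueError(f"merge {i} references unknown cluster {cid}")
                if cid in used:
                    raise ValueError(f"cluster {cid} merged twice")
                used.add(cid)

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    @property
    def heights(self) -> np.ndarray:
        return np.array([h for _, _, h in self.merges])

    def linkage(self) -> np.ndarray:
        """Scipy-compatible ``(n-1, 4)`` linkage matrix (with cluster sizes)."""
        n = self.n_leaves
        sizes = {i: 1 for i in range(n)}
        Z = np.zeros((n - 1, 4))
        for i, (a, b, h) in enumerate(self.merges):
            sizes[n + i] = sizes[a] + sizes[b]
            Z[i] = [a, b, h, sizes[n + i]]
        return Z

    def members(self) -> dict[int, frozenset[int]]:
        """Leaf-index membership of every cluster id."""
        n = self.n_leaves
        out = {i: frozenset([i]) for i in range(n)}
        for i, (a, b, _) in enumerate(self.merges):
            out[n + i] = out[a] | out[b]
        return out

    def write_merges_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("cluster_a\tcluster_b\theight\n")
            for a, b, h in self.merges:
                fh.write(f"{a}\t{b}\t{h:.10g}\n")


def upgma(matrix: DistanceMatrix) -> Dendrogram:
    """Average-linkage agglomerative clustering of a distance matrix.

    The inter-cluster distance is the arithmetic mean over all cross pairs
    (sizes weight the update).  When several pairs attain the minimum, the
    one with the smallest (row, column) position in the current cluster
    order is merged, which makes the output deterministic.
    """
    d = matrix.values.astype(float).copy()
    if np.isnan(d).any():
        raise ValueError("distance matrix contains NaN")
    n = matrix.n_taxa
    active: list[int] = list(range(n))        # cluster ids, in creation order
    sizes = {i: 1 for i in range(n)}
    merges: list[tuple[int, int, float]] = []
    # dist maps frozenset({id_a, id_b}) -> mean inter-cluster distance
    dist = {
        frozenset((active[j], active[k])): float(d[j, k])
        for j in range(n) for k in range(j + 1, n)
    }
    next_id = n
    while len(active) > 1:
        best = None
        for j in range(len(active)):
            for k in range(j + 1, len(active)):
                val = dist[frozenset((active[j], active[k]))]
                if best is None or val < best[0] - 1e-15:
                    best = (val, j, k)
        h, j, k = best
        a, b = active[j], active[k]
        for other in active:
            if other in (a, b):
                continue
            da = dist.pop(frozenset((a, other)))
            db = dist.pop(frozenset((b, other)))
            dist[frozenset((next_id, other))] = (
                sizes[a] * da + sizes[b] * db
            ) / (sizes[a] + sizes[b])
        dist.pop(frozenset((a, b)))
        sizes[next_id] = sizes[a] + sizes[b]
        merges.append((a, b, h))
        active = [c for c in active if c not in (a, b)] + [next_id]
        next_id += 1
    return Dendrogram(tuple(matrix.labels), tuple(merges))


def cophenetic_matrix(tree: Dendrogram) -> DistanceMatrix:
    """Pairwise cophenetic distances: the height of the lowest common merge.

    The convention here is the merge height itself (not twice the leaf-to-
    ancestor branch length); Pearson correlation is scale-invariant, so the
    choice does not affect :func:`cophenetic_correlation`.
    """
    n = tree.n_leaves
    members = tree.members()
    values = np.zeros((n, n))
    for i, (a, b, h) in enumerate(tree.merges):
        for x in members[a]:
            for y in members[b]:
                values[x, y] = values[y, x] = h
    return DistanceMatrix(tree.leaves, values, "cophenetic")


def cophenetic_correlation(
    tree_a: Dendrogram, other: "Dendrogram | DistanceMatrix"
) -> float:
    """Pearson correlation between cophenetic distances, taxa aligned by label.

    ``other`` may be a second dendrogram (tree-vs-tree, the default usage) or
    a distance matrix (the classical dendrogram-vs-source-matrix variant).
    """
    ca = cophenetic_matrix(tree_a)
    if isinstance(other, Dendrogram):
        cb = cophenetic_matrix(other)
    else:
        cb = other
    if set(ca.labels) != set(cb.labels):
        raise ComparabilityError(
            f"leaf sets differ: {sorted(set(ca.labels) ^ set(cb.labels))}"
        )
    cb = cb.reorder(ca.labels)
    x, y = ca.condensed(), cb.condensed()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("cophenetic correlation undefined: zero variance")
    r, _ = stats.pearsonr(x, y)
    return float(r)


def _newick_node(
    tree: Dendrogram, cid: int, parent_height: float, heights: dict[int, float]
) -> tuple[str, str]:
    """Returns (newick fragment, lexicographically smallest leaf under cid)."""
    n = tree.n_leaves
    h = heights[cid]
    length = parent_height / 2 - h / 2
    if cid < n:
        label = tree.leaves[cid]
        return f"{label}:{length:g}", label
    a, b, _ = tree.merges[cid - n]
    fa, la = _newick_node(tree, a, h, heights)
    fb, lb = _newick_node(tree, b, h, heights)
    if lb < la:
        fa, fb, la = fb, fa, lb
    return f"({fa},{fb}):{length:g}", la


def to_newick(tree: Dendrogram) -> str:
    """Rooted Newick with UPGMA branch lengths (root-to-leaf path = height/2).

    Siblings are ordered by their lexicographically smallest descendant leaf
    so the output is byte-stable.
    """
    n = tree.n_leaves
    heights = {i: 0.0 for i in range(n)}
    for i, (_, _, h) in enumerate(tree.merges):
        heights[n + i] = h
    root = n + len(tree.merges) - 1
    frag, _ = _newick_node(tree, root, heights[root], heights)
    # strip the root's zero-length suffix
    frag = frag.rsplit(":", 1)[0]
    return frag + ";"
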