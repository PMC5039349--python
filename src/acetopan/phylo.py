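"""Gene-content distances and the neighbor-joining pan-genome tree.

The distance between two genomes is the Jaccard distance between their sets
of occupied ortholog groups, d = 1 - |A ∩ B| / |A ∪ B|, computed from the
binary presence/absence matrix. The tree is built by classical
neighbor joining: repeatedly join the pair (i, j) minimising
Q(i, j) = (n-2) d(i, j) - sum_k d(i, k) - sum_k d(j, k), with the standard
branch-length formulas; on additive distances this recovers the generating
tree exactly. Ties are broken lexicographically so runs are reproducible.
Negative branch-length estimates are clamped to zero with the deficit moved
to the sibling branch, keeping total path lengths unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import DistanceMatrix as SkbioDistanceMatrix
from skbio import TreeNode


@dataclass
class DistanceMatrix:
    """Symmetric, zero-diagonal distance matrix over genome labels."""

    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match label count")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.d), 0.0):
            raise ValueError("distance matrix must have a zero diagonal")
        if (self.d < 0).any():
            raise ValueError("distances must be nonnegative")

    def to_skbio(self) -> SkbioDistanceMatrix:
        return SkbioDistanceMatrix(self.d, ids=self.labels)

    def write_tsv(self, path) -> None:
        pd.DataFrame(self.d, index=self.labels, columns=self.labels).to_csv(
            path, sep="\t", index_label="genome_id"
        )


def gene_content_distance(matrix: pd.DataFrame) -> DistanceMatrix:
    """Jaccard distances between genome columns of a presence/absence matrix."""
    if matrix.shape[1] < 3:
        raise ValueError("need >= 3 genomes for a distance matrix")
    labels = list(matrix.columns)
    X = matrix.values.astype(bool)
    if not X.any(axis=0).all():
        empty = [labels[i] for i in np.where(~X.any(axis=0))[0]]
        raise ValueError(f"genomes with zero groups: {empty}")
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            inter = np.logical_and(X[:, i], X[:, j]).sum()
            union = np.logical_or(X[:, i], X[:, j]).sum()
            d[i, j] = d[j, i] = 1.0 - inter / union
    return DistanceMatrix(labels=labels, d=d)


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Classical neighbor joining; returns an unrooted tree as a TreeNode
    with a trifurcating root."""
    labels = list(dm.labels)
    n = len(labels)
    if n < 3:
        raise ValueError("neighbor joining needs >= 3 taxa")

    D = dm.d.copy()
    nodes: list[TreeNode] = [TreeNode(name=name) for name in labels]
    # sort key of each active node: lexicographically smallest leaf under it,
    # used only for deterministic tie-breaking
    keys: list[str] = list(labels)

    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        sums = {i: sum(D[i, k] for k in active if k != i) for i in active}
        best = None
        for ai in range(m):
            for bi in range(ai + 1, m):
                i, j = active[ai], active[bi]
                q = (m - 2) * D[i, j] - sums[i] - sums[j]
                tie = tuple(sorted((keys[i], keys[j])))
                if best is None or q < best[0] - 1e-12 or (
                    abs(q - best[0]) <= 1e-12 and tie < best[1]
                ):
                    best = (q, tie, i, j)
        _, _, i, j = best
        li = 0.5 * D[i, j] + (sums[i] - sums[j]) / (2 * (m - 2))
        lj = D[i, j] - li
        # clamp negatives, shifting the deficit onto the sibling branch
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        parent = TreeNode()
        nodes[i].length = max(li, 0.0)
        nodes[j].length = max(lj, 0.0)
        parent.extend([nodes[i], nodes[j]])

        new_row = np.zeros(D.shape[0] + 1)
        D = np.pad(D, ((0, 1), (0, 1)))
        u = D.shape[0] - 1
        for k in active:
            if k in (i, j):
                continue
            D[u, k] = D[k, u] = 0.5 * (D[i, k] + D[j, k] - D[i, j])
        nodes.append(parent)
        keys.append(min(keys[i], keys[j]))
        active = [k for k in active if k not in (i, j)] + [u]

    i, j, k = active
    # final trifurcation branch lengths (three-point formulas)
    li = 0.5 * (D[i, j] + D[i, k] - D[j, k])
    lj = 0.5 * (D[i, j] + D[j, k] - D[i, k])
    lk = 0.5 * (D[i, k] + D[j, k] - D[i, j])
    root = TreeNode()
    for idx, length in ((i, li), (j, lj), (k, lk)):
        nodes[idx].length = max(length, 0.0)
        root.append(nodes[idx])
    return root


def robinson_foulds(tree_a: TreeNode, tree_b: TreeNode) -> float:
    """Unweighted Robinson-Foulds distance between two trees."""
    return tree_a.compare_rfd(tree_b)
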