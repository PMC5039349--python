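"""Ortholog grouping: weighted homology graph + Markov clustering.

The graph is built from filtered directional similarity hits; each unordered
pair carries one undirected edge whose weight is the mean of the two
directional bit scores (a lone direction keeps its single score). Markov
clustering (MCL) runs on the column-stochastic matrix with self-loops set to
the node's maximum incident edge weight, alternating expansion (matrix
square) and inflation (elementwise power, column renormalisation) until the
matrix stabilises; clusters are read off attractor rows. Because expansion
and inflation never mix disconnected components, clustering is performed per
connected component on dense submatrices, which is exact and fast for
family-sized components.

Within each group, members are labelled ortholog or inparalog following the
seed-ortholog convention: in a genome with several members, the member with
the strongest link to another genome is the ortholog, and co-genome members
that are closer to that seed than the seed is to any other genome are its
inparalogs (recent within-genome duplicates).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import networkx as nx
import numpy as np

from .io_formats import GenomePanel, SimilarityHit

WeightTransform = Literal["bit_score", "neg_log10_evalue"]


@dataclass
class HomologyGraph:
    """Undirected weighted homology graph with a node -> genome map."""

    graph: nx.Graph
    genome_of: dict[str, str]

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    def weight(self, u: str, v: str) -> float:
        if self.graph.has_edge(u, v):
            return self.graph[u][v]["weight"]
        return 0.0

    def write_edge_list(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("protein_a\tprotein_b\tweight\n")
            for u, v in sorted(tuple(sorted(e)) for e in self.graph.edges):
                fh.write(f"{u}\t{v}\t{self.graph[u][v]['weight']:.6g}\n")


@dataclass
class OrthologGroup:
    """A gene family: its members, genome occupancy and orthology labels."""

    group_id: str
    members: list[str]
    occupancy: set[str]
    member_labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("empty ortholog group")

    @property
    def size(self) -> int:
        return len(self.members)


def build_homology_graph(
    hits: Iterable[SimilarityHit],
    panel: GenomePanel | None = None,
    weight_transform: WeightTransform = "bit_score",
) -> HomologyGraph:
    """Symmetrize directional hits into an undirected weighted graph.

    When a panel is supplied, all panel proteins become nodes (isolated
    nodes allowed) and hits referencing proteins outside the panel are an
    error. Edge weight is the mean of the directional weights.
    """
    genome_of: dict[str, str] = {}
    graph = nx.Graph()
    if panel is not None:
        for rec in panel.proteins:
            graph.add_node(rec.protein_id)
            genome_of[rec.protein_id] = rec.genome_id

    directional: dict[tuple[str, str], list[float]] = {}
    for hit in hits:
        if panel is not None:
            for pid in (hit.query_id, hit.subject_id):
                if pid not in genome_of:
                    raise ValueError(f"hit references unknown protein {pid!r}")
        if weight_transform == "bit_score":
            w = hit.bit_score
        else:
            w = 300.0 if hit.evalue == 0 else -np.log10(hit.evalue)
        key = tuple(sorted((hit.query_id, hit.subject_id)))
        directional.setdefault(key, []).append(w)

    for (u, v), weights in directional.items():
        graph.add_node(u)
        graph.add_node(v)
        w = float(np.mean(weights))
        if w > 0:
            graph.add_edge(u, v, weight=w)

    if panel is None:
        # genome map unknown for bare hit sets; infer nothing
        genome_of = {n: "" for n in graph.nodes}
    return HomologyGraph(graph=graph, genome_of=genome_of)


def _mcl_dense(
    nodes: Sequence[str],
    weights: np.ndarray,
    inflation: float,
    tolerance: float,
    max_iter: int,
) -> list[list[str]]:
    """Run MCL on one dense (sub)matrix and return its clusters."""
    n = len(nodes)
    M = weights.astype(float).copy()
    # self-loops: max incident edge weight (1 for isolated nodes)
    for i in range(n):
        inc = M[i].max()
        M[i, i] = inc if inc > 0 else 1.0
    M /= M.sum(axis=0, keepdims=True)

    converged = False
    for _ in range(max_iter):
        prev = M
        M = M @ M
        np.power(M, inflation, out=M)
        colsum = M.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        M /= colsum
        if np.max(np.abs(M - prev)) < tolerance:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"MCL did not converge within {max_iter} iterations; "
            "reading clusters from the final matrix"
        )

    eps = 1e-7
    attractors = [i for i in range(n) if M[i, i] > eps]
    if not attractors:  # pathological; every node its own cluster
        return [[name] for name in nodes]
    assignment: dict[int, int] = {}
    for j in range(n):
        best = None
        for i in attractors:
            if M[i, j] > eps:
                key = (M[i, j], nodes[i])
                # higher attractor mass wins; ties to lexicographically
                # smaller attractor id
                if best is None or key[0] > best[0][0] or (
                    key[0] == best[0][0] and key[1] < best[0][1]
                ):
                    best = (key, i)
        assignment[j] = best[1] if best is not None else j
    clusters: dict[int, list[str]] = {}
    for j, i in sorted(assignment.items()):
        clusters.setdefault(i, []).append(nodes[j])
    return [sorted(c) for c in clusters.values()]


def mcl_cluster(
    hg: HomologyGraph,
    inflation: float = 1.5,
    tolerance: float = 1e-6,
    max_iter: int = 200,
) -> list[OrthologGroup]:
    """Markov-cluster the homology graph into ortholog groups.

    Returns one group per cluster; isolated nodes become singletons. Groups
    are numbered in order of their lexicographically smallest member, and
    every node lands in exactly one group.
    """
    if inflation <= 1:
        raise ValueError("inflation must be > 1")
    clusters: list[list[str]] = []
    for comp in nx.connected_components(hg.graph):
        names = sorted(comp)
        if len(names) == 1:
            clusters.append(names)
            continue
        sub = nx.to_numpy_array(hg.graph, nodelist=names, weight="weight")
        clusters.extend(_mcl_dense(names, sub, inflation, tolerance, max_iter))

    clusters.sort(key=lambda c: c[0])
    groups: list[OrthologGroup] = []
    for i, members in enumerate(clusters, start=1):
        occupancy = {hg.genome_of.get(m, "") for m in members} - {""}
        group = OrthologGroup(
            group_id=f"OG{i:05d}", members=members, occupancy=occupancy
        )
        group.member_labels = label_orthology(group, hg)
        groups.append(group)
    return groups


def label_orthology(group: OrthologGroup, hg: HomologyGraph) -> dict[str, str]:
    """Label group members ortholog/inparalog by the seed-ortholog rule."""
    by_genome: dict[str, list[str]] = {}
    for m in group.members:
        by_genome.setdefault(hg.genome_of.get(m, ""), []).append(m)

    labels: dict[str, str] = {}
    for genome, members in by_genome.items():
        if len(members) == 1:
            labels[members[0]] = "ortholog"
            continue

        def best_inter(m: str) -> float:
            return max(
                (
                    hg.weight(m, other)
                    for other in group.members
                    if hg.genome_of.get(other, "") != genome
                ),
                default=0.0,
            )

        seed = min(members, key=lambda m: (-best_inter(m), m))
        seed_inter = best_inter(seed)
        for m in members:
            if m == seed:
                labels[m] = "ortholog"
            elif hg.weight(m, seed) > seed_inter:
                labels[m] = "inparalog"
            else:
                labels[m] = "ortholog"
    return labels


def write_groups_tsv(
    groups: Iterable[OrthologGroup], hg: HomologyGraph, path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("group_id\tprotein_id\tgenome_id\tlabel\n")
        for g in groups:
            for m in g.members:
                fh.write(
                    f"{g.group_id}\t{m}\t{hg.genome_of.get(m, '')}\t"
                    f"{g.member_labels.get(m, 'ortholog')}\n"
                )
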