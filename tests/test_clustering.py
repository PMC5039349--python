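import networkx as nx
import numpy as np
import pytest

from acetopan.clustering import (
    HomologyGraph,
    OrthologGroup,
    build_homology_graph,
    label_orthology,
    mcl_cluster,
)
from acetopan.io_formats import SimilarityHit
from acetopan.pangenome import presence_matrix, partition
from acetopan.similarity import all_vs_all
from acetopan.synthetic import recovery_accuracy


def hit(q, s, bits):
    return SimilarityHit(q, s, bits, 1e-30, 0.9, 200.0)


def graph_from_edges(edges, genome_of=None):
    g = nx.Graph()
    for u, v, w in edges:
        g.add_edge(u, v, weight=w)
    nodes = set(g.nodes)
    if genome_of is None:
        genome_of = {n: "G" for n in nodes}
    for n in genome_of:
        g.add_node(n)
    return HomologyGraph(graph=g, genome_of=genome_of)


def naive_mcl(nodes, weights, inflation, tolerance=1e-6, max_iter=200):
    """Deliberately plain full-matrix MCL used as an independent oracle:
    explicit loops, no per-component decomposition, no tie-break machinery
    beyond the documented mass-then-lexicographic rule."""
    n = len(nodes)
    M = [[float(weights[i][j]) for j in range(n)] for i in range(n)]
    for i in range(n):
        loop = max(M[i])
        M[i][i] = loop if loop > 0 else 1.0
    def normalize(A):
        for j in range(n):
            s = sum(A[i][j] for i in range(n))
            for i in range(n):
                A[i][j] /= s
    normalize(M)
    for _ in range(max_iter):
        prev = [row[:] for row in M]
        sq = [[sum(M[i][k] * M[k][j] for k in range(n)) for j in range(n)]
              for i in range(n)]
        M = [[sq[i][j] ** inflation for j in range(n)] for i in range(n)]
        normalize(M)
        if max(abs(M[i][j] - prev[i][j]) for i in range(n) for j in range(n)) < tolerance:
            break
    eps = 1e-7
    attractors = [i for i in range(n) if M[i][i] > eps]
    assign = {}
    for j in range(n):
        cands = [(M[i][j], nodes[i], i) for i in attractors if M[i][j] > eps]
        if not cands:
            assign[j] = j
        else:
            assign[j] = max(cands, key=lambda t: (t[0], [-ord(c) for c in t[1]]))[2]
    clusters = {}
    for j, i in assign.items():
        clusters.setdefault(i, []).append(nodes[j])
    return sorted(sorted(c) for c in clusters.values())


class TestBuildGraph:
    def test_directional_scores_averaged(self):
        hg = build_homology_graph([hit("a", "b", 100.0), hit("b", "a", 98.0)])
        assert hg.weight("a", "b") == pytest.approx(99.0)

    def test_no_hits_gives_isolated_nodes(self, small_panel_truth):
        panel, _ = small_panel_truth
        hg = build_homology_graph([], panel)
        assert len(hg.graph.nodes) == len(panel.proteins)
        assert len(hg.graph.edges) == 0

    def test_single_direction_keeps_its_score(self):
        hg = build_homology_graph([hit("a", "b", 70.0)])
        assert hg.weight("a", "b") == pytest.approx(70.0)

    def test_unknown_protein_with_panel_is_error(self, small_panel_truth):
        panel, _ = small_panel_truth
        with pytest.raises(ValueError, match="unknown protein"):
            build_homology_graph([hit("nope", "alsonope", 50.0)], panel)


class TestMclCluster:
    def test_two_disjoint_triangles(self):
        hg = graph_from_edges(
            [("a", "b", 1), ("b", "c", 1), ("a", "c", 1),
             ("x", "y", 1), ("y", "z", 1), ("x", "z", 1)]
        )
        groups = mcl_cluster(hg, inflation=2.0)
        assert sorted(g.members for g in groups) == [["a", "b", "c"], ["x", "y", "z"]]

    def test_single_edge(self):
        hg = graph_from_edges([("a", "b", 5.0)])
        (group,) = mcl_cluster(hg, inflation=2.0)
        assert group.members == ["a", "b"]

    def test_six_node_path_splits_in_half(self):
        edges = [("a", "b", 1), ("b", "c", 1), ("c", "d", 1),
                 ("d", "e", 1), ("e", "f", 1)]
        hg = graph_from_edges(edges)
        groups = mcl_cluster(hg, inflation=2.0)
        assert sorted(g.members for g in groups) == [
            ["a", "b", "c"], ["d", "e", "f"]
        ]

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_naive_reference_on_random_graphs(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 11))
        nodes = [f"n{i}" for i in range(n)]
        W = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                if rng.random() < 0.4:
                    W[i, j] = W[j, i] = float(rng.integers(1, 10))
        hg = graph_from_edges(
            [
                (nodes[i], nodes[j], W[i, j])
                for i in range(n)
                for j in range(i + 1, n)
                if W[i, j] > 0
            ],
            genome_of={n_: "G" for n_ in nodes},
        )
        expected = naive_mcl(nodes, W.tolist(), inflation=2.0)
        got = sorted(g.members for g in mcl_cluster(hg, inflation=2.0))
        assert got == expected

    def test_partition_property_and_no_component_merge(self):
        rng = np.random.default_rng(9)
        for _ in range(5):
            g = nx.gnp_random_graph(12, 0.3, seed=int(rng.integers(1e6)))
            g = nx.relabel_nodes(g, {i: f"n{i:02d}" for i in g.nodes})
            for u, v in g.edges:
                g[u][v]["weight"] = float(rng.integers(1, 8))
            hg = HomologyGraph(graph=g, genome_of={n: "G" for n in g.nodes})
            groups = mcl_cluster(hg, inflation=1.5)
            members = [m for grp in groups for m in grp.members]
            assert sorted(members) == sorted(g.nodes)  # exact partition
            comp_of = {}
            for ci, comp in enumerate(nx.connected_components(g)):
                for n_ in comp:
                    comp_of[n_] = ci
            for grp in groups:
                assert len({comp_of[m] for m in grp.members}) == 1

    def test_inflation_below_one_rejected(self):
        hg = graph_from_edges([("a", "b", 1.0)])
        with pytest.raises(ValueError):
            mcl_cluster(hg, inflation=1.0)


class TestLabelOrthology:
    def test_one_member_per_genome_all_orthologs(self):
        hg = graph_from_edges(
            [("a1", "b1", 100.0)], genome_of={"a1": "A", "b1": "B"}
        )
        group = OrthologGroup("OG1", ["a1", "b1"], {"A", "B"})
        assert label_orthology(group, hg) == {"a1": "ortholog", "b1": "ortholog"}

    def test_recent_duplicate_is_inparalog(self):
        # a2 closer to a1 (200) than a1 is to any other genome (150)
        hg = graph_from_edges(
            [("a1", "a2", 200.0), ("a1", "b1", 150.0), ("a2", "b1", 140.0)],
            genome_of={"a1": "A", "a2": "A", "b1": "B"},
        )
        group = OrthologGroup("OG1", ["a1", "a2", "b1"], {"A", "B"})
        labels = label_orthology(group, hg)
        assert labels == {"a1": "ortholog", "a2": "inparalog", "b1": "ortholog"}

    def test_ancient_paralog_stays_ortholog(self):
        # a2's link to the seed (100) is weaker than the seed's best
        # inter-genome link (150): retained as ortholog
        hg = graph_from_edges(
            [("a1", "a2", 100.0), ("a1", "b1", 150.0), ("a2", "b1", 90.0)],
            genome_of={"a1": "A", "a2": "A", "b1": "B"},
        )
        group = OrthologGroup("OG1", ["a1", "a2", "b1"], {"A", "B"})
        labels = label_orthology(group, hg)
        assert labels["a2"] == "ortholog"


def test_truth_recovery_on_low_divergence_panel(diverged_panel_truth):
    """At 5% divergence with no paralogs, clustering recovers the planted
    families exactly."""
    panel, truth = diverged_panel_truth
    hits = all_vs_all(panel)
    hg = build_homology_graph(hits, panel)
    groups = mcl_cluster(hg)
    assert recovery_accuracy(groups, truth) == 1.0
    part = partition(presence_matrix(groups, panel), groups)
    assert part.group_counts == truth.class_counts
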