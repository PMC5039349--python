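"""Term enrichment with Bonferroni correction and kappa-score term grouping.

Over-representation of annotation terms (GO, KEGG or custom) in a study set
against a gene universe is tested with the hypergeometric upper tail; raw
p-values are Bonferroni-corrected over the number of tested terms and a term
is significant when the corrected p is strictly below alpha (default 0.05).
Redundancy between significant terms is measured by Cohen's kappa over the
two terms' gene-membership indicator vectors, and terms are grouped as the
connected components of the graph whose edges are kappa >= threshold
(default 0.4, the usual enrichment-map convention); each group is named by
its most significant (leading) term.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
from scipy.stats import hypergeom


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    k: int  # study-set genes carrying the term
    K: int  # universe genes carrying the term
    n: int  # study-set size
    N: int  # universe size
    p: float
    p_adj: float
    significant: bool


@dataclass
class TermGroup:
    group_id: str
    members: list[str]
    leading_term: str
    kappa_edges: list[tuple[str, str, float]]


def hypergeom_pvalue(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    X counts annotated genes in a size-n draw without replacement from a
    universe of N genes of which K are annotated.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError("require 0 <= K, n <= N")
    if not 0 <= k <= min(K, n):
        raise ValueError("require 0 <= k <= min(K, n)")
    return float(hypergeom.sf(k - 1, N, K, n))


def enrich_terms(
    study_set: set[str],
    annotations: Mapping[str, set[str]],
    universe: set[str],
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Test every term with at least one universe gene for over-representation.

    Bonferroni m = number of tested terms; significance is p_adj < alpha
    (strict).
    """
    if not universe:
        raise ValueError("empty universe")
    if not study_set:
        raise ValueError("empty study set")
    if not study_set <= universe:
        raise ValueError("study set must be a subset of the universe")
    tested = {
        term: genes & universe
        for term, genes in annotations.items()
        if genes & universe
    }
    m = len(tested)
    n, N = len(study_set), len(universe)
    results = []
    for term in sorted(tested):
        genes = tested[term]
        K = len(genes)
        k = len(genes & study_set)
        p = hypergeom_pvalue(k, K, n, N)
        p_adj = min(1.0, m * p)
        results.append(
            EnrichmentResult(term, k, K, n, N, p, p_adj, p_adj < alpha)
        )
    return results


def kappa_score(
    genes_a: set[str], genes_b: set[str], universe: set[str]
) -> float:
    """Cohen's kappa between two terms' membership vectors over the universe.

    Chance-corrected agreement: kappa = (Po - Pe) / (1 - Pe) from the 2x2
    co-membership table. Two terms covering the whole universe agree
    perfectly, so kappa is defined as 1 there.
    """
    if not (genes_a <= universe and genes_b <= universe):
        raise ValueError("term gene sets must be subsets of the universe")
    N = len(universe)
    if N == 0:
        raise ValueError("empty universe")
    both_in = len(genes_a & genes_b)
    both_out = N - len(genes_a | genes_b)
    po = (both_in + both_out) / N
    pa, pb = len(genes_a) / N, len(genes_b) / N
    pe = pa * pb + (1 - pa) * (1 - pb)
    if pe == 1.0:
        return 1.0
    return (po - pe) / (1 - pe)


def group_terms(
    results: Sequence[EnrichmentResult],
    annotations: Mapping[str, set[str]],
    universe: set[str],
    kappa_threshold: float = 0.4,
) -> list[TermGroup]:
    """Group significant terms by kappa-connected components.

    Edges join term pairs with kappa >= threshold; each connected component
    is one group (singletons allowed) led by its minimal-p_adj member, ties
    broken by lexicographic term id. Groups are numbered by ascending
    leading-term p_adj.
    """
    significant = [r for r in results if r.significant]
    if not significant:
        raise ValueError("no significant terms to group")
    padj = {r.term_id: r.p_adj for r in significant}
    graph = nx.Graph()
    terms = sorted(padj)
    graph.add_nodes_from(terms)
    edges: dict[tuple[str, str], float] = {}
    for i, a in enumerate(terms):
        for b in terms[i + 1 :]:
            kappa = kappa_score(
                annotations[a] & universe, annotations[b] & universe, universe
            )
            if kappa >= kappa_threshold:
                graph.add_edge(a, b)
                edges[(a, b)] = kappa

    components = [sorted(c) for c in nx.connected_components(graph)]
    components.sort(key=lambda c: (min(padj[t] for t in c), c[0]))
    groups = []
    for i, members in enumerate(components, start=1):
        leading = min(members, key=lambda t: (padj[t], t))
        kedges = [
            (a, b, w) for (a, b), w in sorted(edges.items()) if a in members
        ]
        groups.append(TermGroup(f"TG{i:03d}", members, leading, kedges))
    return groups


def write_enrichment_tsv(
    results: Iterable[EnrichmentResult], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("term_id\tk\tK\tn\tN\tp\tp_adj\tsignificant\n")
        for r in sorted(results, key=lambda r: (r.p_adj, r.term_id)):
            fh.write(
                f"{r.term_id}\t{r.k}\t{r.K}\t{r.n}\t{r.N}\t{r.p:.6g}\t"
                f"{r.p_adj:.6g}\t{int(r.significant)}\n"
            )


def write_term_groups_tsv(groups: Iterable[TermGroup], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("group_id\tterm_id\tis_leading\n")
        for g in groups:
            for t in g.members:
                fh.write(f"{g.group_id}\t{t}\t{int(t == g.leading_term)}\n")


def write_kappa_edges_tsv(groups: Iterable[TermGroup], path: str | Path) -> None:
    """Edge list of the kappa graph (Cytoscape-importable)."""
    with open(path, "w") as fh:
        fh.write("term_a\tterm_b\tkappa\n")
        for g in groups:
            for a, b, w in g.kappa_edges:
                fh.write(f"{a}\t{b}\t{w:.6g}\n")
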