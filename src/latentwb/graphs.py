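"""Signed-graph biomarkers of fitted GEC matrices.

A fitted GEC is split into a positive and a negative weighted subgraph.
Per-node clique bipartitions (the maximum clique containing the node vs
everything else) yield inter-clique edge statistics; scalar measures
(sparsity, asymmetry, mean/std connectivity) and generic graph metrics
(degree centrality, weighted clustering) complete the biomarker set, and
groups are compared by pairwise two-sample Kolmogorov-Smirnov tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import stats

from .types import InputError, ParameterError

#: |entry| below this threshold counts as "small" in the sparsity measure.
SPARSITY_THRESHOLD = 0.015


@dataclass
class SignedGraphPair:
    positive: nx.DiGraph
    negative: nx.DiGraph  # weights stored as magnitudes, sign flag on edges

    def positive_undirected(self) -> nx.Graph:
        return self.positive.to_undirected()

    def negative_undirected(self) -> nx.Graph:
        return self.negative.to_undirected()


def signed_subgraphs(gec: np.ndarray) -> SignedGraphPair:
    """Split a coupling matrix into positive- and negative-edge subgraphs.

    Directedness is preserved; the diagonal is excluded; negative edges are
    stored with their magnitude as ``weight`` and ``sign=-1``.
    """
    gec = np.asarray(gec, dtype=float)
    n = gec.shape[0]
    if gec.ndim != 2 or gec.shape[1] != n:
        raise InputError("GEC must be square")
    pos = nx.DiGraph()
    neg = nx.DiGraph()
    pos.add_nodes_from(range(n))
    neg.add_nodes_from(range(n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            w = gec[i, j]
            if w > 0:
                pos.add_edge(i, j, weight=w, sign=1)
            elif w < 0:
                neg.add_edge(i, j, weight=-w, sign=-1)
    return SignedGraphPair(pos, neg)


def node_clique_bipartition(graph: nx.Graph, node) -> tuple[frozenset, frozenset]:
    """Maximum clique containing ``node`` and its complement.

    Cliques are enumerated with Bron-Kerbosch (networkx ``find_cliques``
    restricted to the node); among maximum-size cliques the lexicographically
    smallest sorted node set is returned, for determinism.
    """
    if isinstance(graph, nx.DiGraph):
        graph = graph.to_undirected()
    if node not in graph:
        raise ParameterError(f"node {node!r} not in graph")
    best = None
    for clique in nx.find_cliques(graph, nodes=[node]):
        key = (-len(clique), tuple(sorted(clique)))
        if best is None or key < best[0]:
            best = (key, clique)
    clique = frozenset(best[1]) if best else frozenset([node])
    complement = frozenset(graph.nodes) - clique
    return clique, complement


def interclique_stats(gec: np.ndarray):
    """Mean/std of boundary-edge weights between each node's clique and its
    complement, averaged over nodes, separately for the positive and the
    negative subgraph.  Returns (pos_mean, pos_std, neg_mean, neg_std);
    nodes without boundary edges are skipped.
    """
    pair = signed_subgraphs(gec)
    out = []
    for graph, sign in ((pair.positive_undirected(), 1.0),
                        (pair.negative_undirected(), -1.0)):
        means, stds = [], []
        for node in graph.nodes:
            clique, complement = node_clique_bipartition(graph, node)
            if not complement:
                continue
            weights = [sign * d["weight"]
                       for _, _, d in nx.edge_boundary(graph, clique, complement, data=True)]
            if not weights:
                continue
            means.append(np.mean(weights))
            stds.append(np.std(weights))
        out.append((float(np.mean(means)) if means else np.nan,
                    float(np.mean(stds)) if stds else np.nan))
    (pos_mean, pos_std), (neg_mean, neg_std) = out
    return pos_mean, pos_std, neg_mean, neg_std


def within_clique_density(graph: nx.Graph, clique_pair) -> float:
    """Realized edges inside the two cliques over the possible within-clique
    pairs.  Singleton cliques have no within-clique pair and are an error."""
    if isinstance(graph, nx.DiGraph):
        graph = graph.to_undirected()
    c1, c2 = (set(c) for c in clique_pair)
    if not c1 or not c2:
        raise ParameterError("cliques must be non-empty")
    possible = sum(len(c) * (len(c) - 1) // 2 for c in (c1, c2))
    if possible == 0:
        raise ParameterError("singleton cliques have undefined density")
    realized = sum(
        1
        for c in (c1, c2)
        for u, v in graph.subgraph(c).edges
    )
    return realized / possible


def graph_bipartition_density(gec: np.ndarray, sign: str = "positive") -> float:
    """Within-clique density of the signed subgraph, averaged over the
    per-node maximum-clique bipartitions (skipping degenerate ones)."""
    pair = signed_subgraphs(gec)
    graph = (pair.positive_undirected() if sign == "positive"
             else pair.negative_undirected())
    vals = []
    for node in graph.nodes:
        clique, complement = node_clique_bipartition(graph, node)
        if len(clique) < 2 or not complement:
            continue
        try:
            vals.append(within_clique_density(graph, (clique, complement)))
        except ParameterError:
            continue
    return float(np.mean(vals)) if vals else np.nan


def centrality_and_clustering(graph: nx.Graph) -> tuple[float, float]:
    """Mean degree centrality and mean weighted clustering coefficient."""
    if isinstance(graph, nx.DiGraph):
        graph = graph.to_undirected()
    if graph.number_of_nodes() == 0:
        raise ParameterError("empty graph")
    centrality = np.mean(list(nx.degree_centrality(graph).values()))
    clustering = np.mean(list(nx.clustering(graph, weight="weight").values()))
    return float(centrality), float(clustering)


@dataclass
class GraphScalars:
    sparsity: float
    asymmetry: float
    mean_conn: float
    std_conn: float


def gec_scalars(gec: np.ndarray) -> GraphScalars:
    """Scalar GEC measures.

    sparsity: fraction of entries with |value| < 0.015; asymmetry:
    mean(|GEC - GEC^T|)/2 (halved to correct the double count of each
    unordered pair); mean/std over all entries.
    """
    gec = np.asarray(gec, dtype=float)
    if gec.ndim != 2 or gec.shape[0] != gec.shape[1]:
        raise InputError("GEC must be square")
    n2 = gec.size
    sparsity = float(np.count_nonzero(np.abs(gec) < SPARSITY_THRESHOLD) / n2)
    asymmetry = float(np.mean(np.abs(gec - gec.T)) / 2.0)
    return GraphScalars(
        sparsity=sparsity,
        asymmetry=asymmetry,
        mean_conn=float(gec.mean()),
        std_conn=float(gec.std()),
    )


#: Star annotation thresholds for pairwise tests.
_STARS = ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*"))


def significance_stars(p: float) -> str:
    for threshold, stars in _STARS:
        if p <= threshold:
            return stars
    return "ns"


def compare_groups(values_by_group: dict) -> dict:
    """Pairwise two-sample Kolmogorov-Smirnov tests between groups.

    Returns {(group_a, group_b): {"statistic", "p", "stars"}} for each
    unordered pair (groups sorted within the key).
    """
    groups = sorted(values_by_group)
    if len(groups) < 2:
        raise ParameterError("need at least two groups")
    for g in groups:
        if len(values_by_group[g]) < 3:
            raise ParameterError(f"group {g!r} has fewer than 3 values")
    out = {}
    for i, a in enumerate(groups):
        for b in groups[i + 1:]:
            xa = np.asarray(values_by_group[a], dtype=float)
            xb = np.asarray(values_by_group[b], dtype=float)
            if xa.shape == xb.shape and np.array_equal(np.sort(xa), np.sort(xb)):
                stat, p = 0.0, 1.0
            else:
                res = stats.ks_2samp(xa, xb)
                stat, p = float(res.statistic), float(res.pvalue)
            out[(a, b)] = {"statistic": stat, "p": p, "stars": significance_stars(p)}
    return out
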