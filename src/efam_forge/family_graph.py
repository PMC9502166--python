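"""Protein similarity graph construction and clustering into families.

All-vs-all tabular hits are filtered (e-value, mutual coverage, minimum
length), transformed to ``min(-log10(evalue), ceiling)`` edge weights,
and clustered two ways: a cohesiveness-greedy grower that permits
overlapping clusters, and Markov clustering by alternating expansion and
inflation of a column-stochastic flow matrix.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .protein_filter import HomologyHit

logger = logging.getLogger(__name__)

EVALUE_MAX = 1e-5
MIN_COVERAGE = 0.70
MIN_LENGTH_AA = 50
WEIGHT_CEILING = 200.0


@dataclass
class ClusterSet:
    clusters: list[list[str]]
    algorithm: str
    params: dict = field(default_factory=dict)
    min_size: int = 2
    singleton_count: int = 0
    converged: bool = True

    def __post_init__(self) -> None:
        self.clusters = [sorted(c) for c in self.clusters]
        self.clusters.sort(key=lambda c: (-len(c), c))

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def membership(self) -> dict[str, list[int]]:
        out: dict[str, list[int]] = {}
        for i, c in enumerate(self.clusters):
            for m in c:
                out.setdefault(m, []).append(i)
        return out

    def sizes(self) -> list[int]:
        return [len(c) for c in self.clusters]


def build_graph(
    hits: Iterable[HomologyHit],
    evalue_max: float = EVALUE_MAX,
    min_cov: float = MIN_COVERAGE,
    min_len: int = MIN_LENGTH_AA,
    ceiling: float = WEIGHT_CEILING,
) -> nx.Graph:
    """Filter hits and build the weighted undirected similarity graph.

    A hit survives iff its e-value is <= `evalue_max`, the alignment
    covers >= `min_cov` of BOTH sequences, both sequences are at least
    `min_len` residues, and it is not a self-hit.  Weight is
    ``-log10(evalue)`` capped at `ceiling` (e-value 0 maps to the cap);
    non-positive weights are dropped and reciprocal duplicates collapse
    to the maximum weight.
    """
    g = nx.Graph()
    for h in hits:
        if h.query_id == h.subject_id:
            continue
        if h.evalue > evalue_max:
            continue
        if h.qlen < min_len or h.slen < min_len:
            continue
        if h.aln_len / h.qlen < min_cov or h.aln_len / h.slen < min_cov:
            continue
        if h.evalue <= 0.0:
            w = ceiling
        else:
            w = min(-math.log10(h.evalue), ceiling)
        if w <= 0.0:
            continue
        u, v = sorted((h.query_id, h.subject_id))
        if g.has_edge(u, v):
            if w > g[u][v]["weight"]:
                g[u][v]["weight"] = w
        else:
            g.add_edge(u, v, weight=w)
    return g


# ---------------------------------------------------------------------------
# Markov clustering
# ---------------------------------------------------------------------------


def _flow_matrix(graph: nx.Graph, nodes: Sequence[str]) -> np.ndarray:
    """Adjacency with per-node self-loops (max incident weight), column
    normalized."""
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    m = np.zeros((n, n))
    for u, v, data in graph.edges(data=True):
        w = data["weight"]
        m[idx[u], idx[v]] = w
        m[idx[v], idx[u]] = w
    loops = m.max(axis=0)
    loops[loops == 0] = 1.0
    np.fill_diagonal(m, loops)
    return m / m.sum(axis=0, keepdims=True)


def _interpret_clusters(
    m: np.ndarray, nodes: Sequence[str], eps: float = 1e-7
) -> list[set[str]]:
    """Connected components of the converged flow's non-zero structure."""
    adj = (m > eps) | (m.T > eps)
    np.fill_diagonal(adj, True)
    comp = nx.Graph()
    comp.add_nodes_from(range(len(nodes)))
    rows, cols = np.nonzero(adj)
    comp.add_edges_from(zip(rows.tolist(), cols.tolist()))
    return [
        {nodes[i] for i in cc} for cc in nx.connected_components(comp)
    ]


def mcl_cluster(
    graph: nx.Graph,
    inflation: float = 2.0,
    prune: float = 1e-5,
    max_iter: int = 100,
    tol: float = 1e-6,
    min_size: int = 2,
) -> ClusterSet:
    """Markov clustering: expansion (matrix squaring) alternated with
    inflation (entrywise power + column renormalization), with pruning
    of entries below `prune`.  Clusters are the connected components of
    the converged flow; singletons are counted but not reported.
    """
    if graph.number_of_nodes() == 0:
        return ClusterSet([], "mcl", {"inflation": inflation}, min_size)
    nodes = sorted(graph.nodes)
    m = _flow_matrix(graph, nodes)
    converged = False
    for _ in range(max_iter):
        expanded = m @ m
        inflated = np.power(expanded, inflation)
        inflated[inflated < prune] = 0.0
        colsum = inflated.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        inflated /= colsum
        if np.abs(inflated - m).max() < tol:
            m = inflated
            converged = True
            break
        m = inflated
    if not converged:
        logger.warning("MCL did not converge in %d iterations", max_iter)
    groups = _interpret_clusters(m, nodes)
    clusters = [sorted(g) for g in groups if len(g) >= min_size]
    singletons = sum(1 for g in groups if len(g) < min_size)
    return ClusterSet(
        clusters,
        "mcl",
        {"inflation": inflation, "prune": prune, "tol": tol},
        min_size=min_size,
        singleton_count=singletons,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# Cohesiveness-greedy clustering
# ---------------------------------------------------------------------------


def cohesiveness(graph: nx.Graph, members: set[str], penalty: float = 2.0) -> float:
    """W_in / (W_in + W_bound + penalty * |C|)."""
    if not members:
        return 0.0
    w_in = 0.0
    w_bound = 0.0
    for u in members:
        for v, data in graph[u].items():
            if v in members:
                w_in += data["weight"]
            else:
                w_bound += data["weight"]
    w_in /= 2.0
    denom = w_in + w_bound + penalty * len(members)
    return w_in / denom if denom > 0 else 0.0


def _weighted_density(graph: nx.Graph, members: set[str]) -> float:
    n = len(members)
    if n < 2:
        return 0.0
    w_in = sum(
        data["weight"]
        for u, v, data in graph.subgraph(members).edges(data=True)
    )
    return w_in / (n * (n - 1) / 2)


def _grow_cluster(graph: nx.Graph, seed: str, penalty: float) -> set[str]:
    members = {seed}
    score = cohesiveness(graph, members, penalty)
    while True:
        best_move: tuple[str, str] | None = None
        best_score = score
        boundary = sorted(
            {v for u in members for v in graph[u] if v not in members}
        )
        for v in boundary:
            cand = cohesiveness(graph, members | {v}, penalty)
            if cand > best_score + 1e-12:
                best_score = cand
                best_move = ("add", v)
        if len(members) > 1:
            for v in sorted(members):
                cand = cohesiveness(graph, members - {v}, penalty)
                if cand > best_score + 1e-12:
                    best_score = cand
                    best_move = ("remove", v)
        if best_move is None:
            return members
        op, v = best_move
        if op == "add":
            members.add(v)
        else:
            members.remove(v)
        score = best_score


def overlap_score(a: set[str], b: set[str]) -> float:
    """omega(A,B) = |A∩B|^2 / (|A|·|B|)."""
    inter = len(a & b)
    if inter == 0:
        return 0.0
    return inter * inter / (len(a) * len(b))


def _merge_overlapping(
    clusters: list[set[str]], threshold: float
) -> list[set[str]]:
    merge_graph = nx.Graph()
    merge_graph.add_nodes_from(range(len(clusters)))
    for i in range(len(clusters)):
        for j in range(i + 1, len(clusters)):
            if overlap_score(clusters[i], clusters[j]) >= threshold:
                merge_graph.add_edge(i, j)
    merged = []
    for cc in nx.connected_components(merge_graph):
        group: set[str] = set()
        for i in cc:
            group |= clusters[i]
        merged.append(group)
    return merged


def cone_cluster(
    graph: nx.Graph,
    min_size: int = 2,
    penalty: float = 2.0,
    min_density: float = 0.3,
    overlap_merge: float = 0.8,
) -> ClusterSet:
    """Greedy cohesiveness clustering with overlap merging.

    Seeds are taken in decreasing order of total incident edge weight
    over nodes not yet assigned to any cluster; each seed is grown by
    the single best add/remove move until no move improves
    cohesiveness.  Highly overlapping candidates are merged and
    under-sized or sparse clusters discarded.
    """
    if graph.number_of_nodes() == 0:
        return ClusterSet([], "cone", {"penalty": penalty}, min_size)
    strength = {
        v: sum(d["weight"] for d in graph[v].values()) for v in graph.nodes
    }
    order = sorted(graph.nodes, key=lambda v: (-strength[v], v))
    assigned: set[str] = set()
    candidates: list[set[str]] = []
    for seed in order:
        if seed in assigned:
            continue
        members = _grow_cluster(graph, seed, penalty)
        candidates.append(members)
        assigned |= members
    merged = _merge_overlapping(candidates, overlap_merge)
    kept = [
        c
        for c in merged
        if len(c) >= min_size and _weighted_density(graph, c) >= min_density
    ]
    covered = set().union(*kept) if kept else set()
    singletons = len(set(graph.nodes) - covered)
    return ClusterSet(
        [sorted(c) for c in kept],
        "cone",
        {
            "penalty": penalty,
            "min_density": min_density,
            "overlap_merge": overlap_merge,
        },
        min_size=min_size,
        singleton_count=singletons,
    )


# ---------------------------------------------------------------------------
# Clustering comparison
# ---------------------------------------------------------------------------


def adjusted_rand_index(labels_a: Sequence[int], labels_b: Sequence[int]) -> float:
    """ARI from the pair-counting contingency table."""
    if len(labels_a) != len(labels_b):
        raise ValueError("label vectors differ in length")
    n = len(labels_a)
    if n == 0:
        return 1.0
    from collections import Counter

    contingency: Counter[tuple[int, int]] = Counter(zip(labels_a, labels_b))
    a_marg = Counter(labels_a)
    b_marg = Counter(labels_b)

    def comb2(x: int) -> float:
        return x * (x - 1) / 2

    sum_ij = sum(comb2(v) for v in contingency.values())
    sum_a = sum(comb2(v) for v in a_marg.values())
    sum_b = sum(comb2(v) for v in b_marg.values())
    total = comb2(n)
    expected = sum_a * sum_b / total if total else 0.0
    max_index = (sum_a + sum_b) / 2
    if max_index == expected:
        return 1.0
    return (sum_ij - expected) / (max_index - expected)


def _partition_labels(cs: ClusterSet, nodes: Sequence[str]) -> list[int]:
    """Non-overlapping label vector; overlapping members take their first
    cluster, unassigned nodes get unique singleton labels."""
    label: dict[str, int] = {}
    for i, c in enumerate(cs.clusters):
        for m in c:
            label.setdefault(m, i)
    next_label = len(cs.clusters)
    out = []
    for v in nodes:
        if v not in label:
            label[v] = next_label
            next_label += 1
        out.append(label[v])
    return out


def compare_clusterings(a: ClusterSet, b: ClusterSet) -> dict:
    """Cluster counts, size statistics and ARI over the shared node set."""
    nodes_a = set(a.membership())
    nodes_b = set(b.membership())
    universe = sorted(nodes_a | nodes_b)
    if universe and not (nodes_a & nodes_b):
        raise ValueError("clusterings share no nodes")
    ari = adjusted_rand_index(
        _partition_labels(a, universe), _partition_labels(b, universe)
    )

    def stats(cs: ClusterSet) -> dict:
        sizes = cs.sizes()
        return {
            "n_clusters": cs.n_clusters,
            "sizes": sorted(sizes, reverse=True),
            "mean_size": float(np.mean(sizes)) if sizes else 0.0,
            "median_size": float(np.median(sizes)) if sizes else 0.0,
            "singleton_count": cs.singleton_count,
        }

    return {"a": stats(a), "b": stats(b), "ari": ari}
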