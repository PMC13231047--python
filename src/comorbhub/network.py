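"""Scored PPI network analysis: centrality pre-filtering, MCODE molecular
complex detection, maximal clique centrality (MCC) ranking, and hub
triangulation.

MCODE follows the original three-stage molecular-complex-detection scheme
(vertex weighting by core-clustering coefficient, greedy complex growth
from high-weight seeds, haircut post-processing); the cluster score is
graph density times node count. MCC(v) is the sum over all maximal cliques
containing v of (clique size - 1)!.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from . import io as chio

__all__ = [
    "MCODECluster",
    "load_network",
    "centralities",
    "mcode",
    "cluster_score",
    "mcc",
    "triangulate",
]


@dataclass
class MCODECluster:
    members: list[str]
    edge_count: int
    score: float
    seed: str
    rank: int = 0


def load_network(path_or_edges, min_score: float = 0.4) -> nx.Graph:
    """Build a simple undirected graph from a STRING-dialect edge table.

    Scores on the 0-1000 integer scale are divided by 1000; edges with
    score < ``min_score`` (inclusive threshold: score >= min_score kept)
    are dropped, duplicate edges keep the maximum score, self-loops and
    isolated nodes are removed.
    """
    if isinstance(path_or_edges, pd.DataFrame):
        edges = path_or_edges
    else:
        edges = chio.read_edge_table(path_or_edges)
    scores = pd.to_numeric(edges["combined_score"], errors="raise")
    if (scores > 1000).any() or (scores < 0).any():
        raise ValueError("combined_score outside the 0-1000 scale")
    g = nx.Graph()
    for n1, n2, s in zip(edges["node1"], edges["node2"], scores / 1000.0):
        n1, n2 = str(n1), str(n2)
        if n1 == n2:
            continue
        if s < min_score:
            continue
        if g.has_edge(n1, n2):
            g[n1][n2]["combined_score"] = max(g[n1][n2]["combined_score"], float(s))
        else:
            g.add_edge(n1, n2, combined_score=float(s))
    g.remove_nodes_from(list(nx.isolates(g)))
    return g


def centralities(net: nx.Graph) -> pd.DataFrame:
    """Degree, normalized betweenness and (Wasserman-Faust) closeness per
    node, with an ``above_average`` flag set when all three strictly exceed
    their network-wide means."""
    if net.number_of_nodes() < 3:
        raise ValueError("need >=3 nodes")
    deg = dict(net.degree())
    btw = nx.betweenness_centrality(net, normalized=True)
    clo = nx.closeness_centrality(net, wf_improved=True)
    table = pd.DataFrame(
        {
            "degree": pd.Series(deg, dtype=float),
            "betweenness": pd.Series(btw),
            "closeness": pd.Series(clo),
        }
    ).sort_index()
    means = table.mean(axis=0)
    table["above_average"] = (
        (table["degree"] > means["degree"])
        & (table["betweenness"] > means["betweenness"])
        & (table["closeness"] > means["closeness"])
    )
    return table


def cluster_score(n: int, m: int) -> float:
    """MCODE cluster score: density * node count = (2m / (n (n-1))) * n,
    reported to 3 decimals."""
    if n < 2:
        raise ValueError("cluster score requires >= 2 nodes")
    if not 0 <= m <= n * (n - 1) // 2:
        raise ValueError("edge count out of range")
    return round(2.0 * m / (n * (n - 1)) * n, 3)


def _highest_k_core(g: nx.Graph) -> tuple[nx.Graph, int]:
    core_num = nx.core_number(g)
    if not core_num:
        return g, 0
    kmax = max(core_num.values())
    nodes = [v for v, c in core_num.items() if c >= kmax]
    return g.subgraph(nodes), kmax


def _vertex_weights(net: nx.Graph, degree_cutoff: int) -> dict[str, float]:
    weights = {}
    for v in net.nodes:
        if net.degree(v) < degree_cutoff:
            weights[v] = 0.0
            continue
        nb = list(net.neighbors(v)) + [v]
        sub = net.subgraph(nb)
        core, k = _highest_k_core(sub)
        n = core.number_of_nodes()
        density = (
            2.0 * core.number_of_edges() / (n * (n - 1)) if n > 1 else 0.0
        )
        weights[v] = density * k
    return weights


def mcode(
    net: nx.Graph,
    degree_cutoff: int = 2,
    k_core: int = 2,
    node_score_cutoff: float = 0.2,
    haircut: bool = True,
    fluff: bool = False,
) -> list[MCODECluster]:
    """Molecular complex detection.

    Stage 1: weight each vertex by (density of the highest k-core of its
    closed neighborhood) * k. Stage 2: grow complexes breadth-first from
    the highest-weight unvisited seed, admitting neighbors whose weight is
    >= seed weight * (1 - node_score_cutoff). Stage 3: drop complexes
    lacking a ``k_core``-core and, with haircut, iteratively strip
    degree-1 members. Fluff is not implemented (parameter kept for
    interface fidelity; must stay False).
    """
    if fluff:
        raise NotImplementedError("fluff post-processing is not provided")
    weights = _vertex_weights(net, degree_cutoff)
    visited: set = set()
    complexes: list[tuple[list, str]] = []
    for seed in sorted(net.nodes, key=lambda v: (-weights[v], str(v))):
        if seed in visited or weights[seed] <= 0:
            continue
        threshold = weights[seed] * (1.0 - node_score_cutoff)
        members = {seed}
        frontier = [seed]
        visited.add(seed)
        while frontier:
            nxt = []
            for u in frontier:
                for w in sorted(net.neighbors(u), key=str):
                    if w in visited:
                        continue
                    if weights[w] >= threshold:
                        visited.add(w)
                        members.add(w)
                        nxt.append(w)
            frontier = nxt
        complexes.append((sorted(members, key=str), seed))

    clusters = []
    for members, seed in complexes:
        sub = net.subgraph(members).copy()
        core = nx.k_core(sub, k=k_core)
        if core.number_of_nodes() == 0:
            continue
        if haircut:
            while True:
                leaves = [v for v in sub.nodes if sub.degree(v) <= 1]
                if not leaves:
                    break
                sub.remove_nodes_from(leaves)
        if sub.number_of_nodes() < 2:
            continue
        n, m = sub.number_of_nodes(), sub.number_of_edges()
        clusters.append(
            MCODECluster(
                members=sorted(sub.nodes, key=str),
                edge_count=m,
                score=cluster_score(n, m),
                seed=seed,
            )
        )
    clusters.sort(key=lambda c: (-c.score, str(c.seed)))
    for i, c in enumerate(clusters, 1):
        c.rank = i
    return clusters


def mcc(net: nx.Graph, top_n: int = 20, clique_budget: int = 10**6) -> pd.DataFrame:
    """Maximal clique centrality ranking.

    MCC(v) = sum over maximal cliques C (|C| >= 2) containing v of
    (|C| - 1)!. For a node whose neighborhood has no internal edges this
    equals its degree. Ties at the ``top_n`` boundary are all included
    (flagged) and a warning records the overflow.
    """
    scores = {v: 0 for v in net.nodes}
    n_cliques = 0
    for clique in nx.find_cliques(net):
        n_cliques += 1
        if n_cliques > clique_budget:
            raise RuntimeError(
                "maximal-clique budget exceeded; retry with a degeneracy-"
                "ordered enumeration or a sparser score threshold"
            )
        if len(clique) < 2:
            continue
        contrib = math.factorial(len(clique) - 1)
        for v in clique:
            scores[v] += contrib
    table = pd.DataFrame({"mcc": pd.Series(scores, dtype=float)})
    table = table.sort_values(
        by=["mcc"], ascending=False, kind="mergesort"
    )
    table = table.loc[sorted(table.index, key=str)].sort_values(
        by="mcc", ascending=False, kind="mergesort"
    )
    table["rank"] = range(1, len(table) + 1)
    if len(table) <= top_n:
        table["top20"] = True
    else:
        cutoff = table["mcc"].iloc[top_n - 1]
        table["top20"] = table["mcc"] >= cutoff
        if int(table["top20"].sum()) > top_n:
            warnings.warn(
                f"MCC ties at rank {top_n}: keeping "
                f"{int(table['top20'].sum())} nodes",
                stacklevel=2,
            )
    return table


def triangulate(
    cent: pd.DataFrame, mcode_top: MCODECluster | None, mcc_rank: pd.DataFrame
) -> list[str]:
    """Key hub genes: nodes above average on all three centralities AND in
    the top MCODE cluster AND in the MCC top set."""
    pre = set(cent.index[cent["above_average"]])
    top_cluster = set(mcode_top.members) if mcode_top is not None else set()
    top_mcc = set(mcc_rank.index[mcc_rank["top20"]])
    return sorted(pre & top_cluster & top_mcc)
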