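"""Seed-anchored PPI network integration.

Seed proteins are those changing concordantly in expression and inferred
activity.  The integrated subnetwork is the union of *all* unweighted
shortest paths (geodesics) between every seed pair, computed from BFS
distance fields; STRING scores only gate edge retention upstream, paths are
hop-count geodesics.  Significance comes from a Fisher test for enrichment
of significant non-seed proteins plus degree-preserving rewired nulls.
Communities are Louvain partitions whose activity is the count of
up-regulated minus down-regulated members.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .activity import ActivityResult
from .compare import OverlapResult, jaccard_index, overlap_test
from .diffexp import ContrastResult

logger = logging.getLogger(__name__)


@dataclass
class SeedSet:
    """Direction-concordant significant proteins anchoring the integration."""

    table: pd.DataFrame  # index: protein; columns: direction, log2fc, expr_q, nes, act_q

    @property
    def proteins(self) -> list:
        return list(self.table.index)

    def direction(self, protein) -> str:
        return self.table.loc[protein, "direction"]

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class IntegratedGraph:
    """Geodesic subnetwork with per-node direction/evidence and centrality."""

    graph: nx.Graph
    nodes: pd.DataFrame  # columns: direction, evidence, degree, betweenness, importance

    def __post_init__(self) -> None:
        self.nodes = self.nodes.sort_index()


@dataclass
class ClusterSet:
    """Louvain partition with per-community activity scores."""

    clusters: list  # list of frozensets
    activity: pd.DataFrame  # index cluster id; columns n_up, n_down, score, label
    modularity: float = field(default=np.nan)

    def membership(self) -> dict:
        out = {}
        for ci, members in enumerate(self.clusters):
            for m in members:
                out[m] = ci
        return out


def select_seeds(
    expr: ContrastResult,
    act: ActivityResult,
    fdr: float = 0.10,
    nes_min: float = 5.0,
) -> SeedSet:
    """Proteins with expression q < fdr, activity q < fdr, |NES| > nes_min and
    matching signs of log2FC and NES."""
    shared = expr.table.index.intersection(act.table.index)
    e = expr.table.loc[shared]
    a = act.table.loc[shared]
    keep = (
        (e["qval"] < fdr)
        & (a["qval"] < fdr)
        & (a["nes"].abs() > nes_min)
        & (np.sign(e["log2fc"]) == np.sign(a["nes"]))
        & (e["log2fc"] != 0)
    )
    sel = shared[keep.to_numpy(dtype=bool)]
    table = pd.DataFrame(
        {
            "direction": np.where(e.loc[sel, "log2fc"] > 0, "up", "down"),
            "log2fc": e.loc[sel, "log2fc"],
            "expr_q": e.loc[sel, "qval"],
            "nes": a.loc[sel, "nes"],
            "act_q": a.loc[sel, "qval"],
        },
        index=sel,
    )
    if table.empty:
        logger.warning("no seed protein satisfies the concordance criteria")
    return SeedSet(table)


def _geodesic_members(graph: nx.Graph, source, target, dist_s: dict, dist_t: dict):
    """Nodes and edges lying on at least one shortest source-target path."""
    d = dist_s.get(target)
    if d is None:
        return None, None
    nodes = {
        v
        for v in dist_s
        if v in dist_t and dist_s[v] + dist_t[v] == d
    }
    edges = set()
    for u in nodes:
        du = dist_s[u]
        for v in graph[u]:
            if v in nodes and dist_s.get(v) == du + 1 and dist_t.get(v) == dist_t[u] - 1:
                edges.add(frozenset((u, v)))
    return nodes, edges


def geodesic_subgraph(
    ppi: nx.Graph,
    seeds: SeedSet,
    directions: dict | None = None,
    significant: set | None = None,
) -> IntegratedGraph:
    """Union of all shortest paths between every pair of mapped seeds.

    Seeds absent from the PPI are dropped with a log entry; seed pairs in
    different components are skipped.  Node statistics (degree, normalised
    betweenness, importance = degree x betweenness) are computed on the
    extracted subgraph.
    """
    mapped = [s for s in seeds.proteins if s in ppi]
    dropped = set(seeds.proteins) - set(mapped)
    if dropped:
        logger.info("seeds not in PPI dropped: %s", sorted(dropped))
    if len(mapped) < 2:
        raise ValueError("need at least 2 seeds mapped onto the PPI")
    dist = {s: nx.single_source_shortest_path_length(ppi, s) for s in mapped}
    nodes, edges = set(), set()
    for s, t in itertools.combinations(mapped, 2):
        pn, pe = _geodesic_members(ppi, s, t, dist[s], dist[t])
        if pn is None:
            logger.info("seed pair (%s, %s) disconnected; skipped", s, t)
            continue
        nodes |= pn
        edges |= pe
    sub = nx.Graph()
    sub.add_nodes_from(nodes)
    for e in edges:
        u, v = tuple(e)
        sub.add_edge(u, v, **ppi.get_edge_data(u, v, default={}))
    return _annotate(sub, seeds, directions, significant)


def _annotate(
    sub: nx.Graph, seeds: SeedSet, directions: dict | None, significant: set | None
) -> IntegratedGraph:
    directions = directions or {}
    significant = significant or set()
    betw = nx.betweenness_centrality(sub, normalized=True)
    seed_set = set(seeds.proteins)
    rows = {}
    for node in sub.nodes:
        if node in seed_set:
            evidence = "seed"
            direction = seeds.direction(node)
        elif node in significant:
            evidence = "significant-nonseed"
            direction = directions.get(node, "none")
        else:
            evidence = "connector"
            direction = directions.get(node, "none")
        k = sub.degree(node)
        rows[node] = (direction, evidence, k, betw[node], k * betw[node])
    nodes = pd.DataFrame.from_dict(
        rows, orient="index",
        columns=["direction", "evidence", "degree", "betweenness", "importance"],
    )
    return IntegratedGraph(sub, nodes)


def rewire_null(
    ppi: nx.Graph, n_networks: int = 10, swaps_per_edge: int = 10, seed: int = 0
) -> list[nx.Graph]:
    """Degree-preserving randomised copies via double-edge swaps.

    Each null attempts ``swaps_per_edge * |E|`` swaps, rejecting any that
    would create a self-loop or multi-edge; the degree sequence is preserved
    exactly.  Rigid graphs (no admissible swap) are returned unchanged.
    """
    if ppi.number_of_edges() < 2:
        raise ValueError("rewiring needs at least 2 edges")
    nulls = []
    for i in range(n_networks):
        g = ppi.copy()
        nswap = swaps_per_edge * g.number_of_edges()
        try:
            nx.double_edge_swap(g, nswap=nswap, max_tries=100 * nswap, seed=seed + i)
        except (nx.NetworkXAlgorithmError, nx.NetworkXError):
            # rigid graphs (e.g. a triangle) admit no valid swap
            logger.info("rewiring stopped early; graph returned as rewired so far")
        nulls.append(g)
    return nulls


def subgraph_enrichment(
    graph: IntegratedGraph,
    significant: set,
    background: set,
    seeds: SeedSet | None = None,
    null_sizes: list | None = None,
) -> OverlapResult:
    """Fisher enrichment of significant non-seed proteins in the subgraph.

    The 2x2 table crosses (in subgraph) x (significant) over the background
    (all PPI nodes) minus the seeds.  ``null_sizes`` (node counts of the
    geodesic subgraphs on rewired nulls) additionally yield an empirical
    size p-value, attached as ``empirical_size_p``.
    """
    seed_nodes = set(seeds.proteins) if seeds is not None else {
        n for n, row in graph.nodes.iterrows() if row["evidence"] == "seed"
    }
    universe = set(background) - seed_nodes
    in_graph = (set(graph.graph.nodes) - seed_nodes) & universe
    sig = set(significant) & universe
    result = overlap_test(in_graph, sig, len(universe))
    if null_sizes is not None:
        size = graph.graph.number_of_nodes()
        greater = sum(1 for s in null_sizes if s >= size)
        result.empirical_size_p = (1 + greater) / (1 + len(null_sizes))
    return result


def louvain_cluster(
    graph: IntegratedGraph | nx.Graph,
    directions: dict | pd.Series | None = None,
    resolution: float = 1.0,
    seed: int = 0,
) -> ClusterSet:
    """Louvain community detection with per-community activity scores."""
    g = graph.graph if isinstance(graph, IntegratedGraph) else graph
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    if directions is None and isinstance(graph, IntegratedGraph):
        directions = graph.nodes["direction"]
    directions = dict(directions) if directions is not None else {}
    communities = nx.community.louvain_communities(
        g, resolution=resolution, seed=seed, weight=None
    )
    communities = sorted((frozenset(c) for c in communities), key=lambda c: sorted(c)[0])
    q = nx.community.modularity(g, communities, weight=None) if g.number_of_edges() else 0.0
    rows = []
    for members in communities:
        n_up, n_down, score, label = cluster_activity(members, directions)
        rows.append((n_up, n_down, score, label, len(members)))
    act = pd.DataFrame(rows, columns=["n_up", "n_down", "score", "label", "size"])
    return ClusterSet(list(communities), act, float(q))


def cluster_activity(members, directions: dict):
    """(N_up, N_down, A_c = N_up - N_down, label); ties are 'balanced'."""
    n_up = sum(1 for m in members if directions.get(m) == "up")
    n_down = sum(1 for m in members if directions.get(m) == "down")
    score = n_up - n_down
    label = "up" if score > 0 else ("down" if score < 0 else "balanced")
    return n_up, n_down, score, label


def match_clusters(cs_a: ClusterSet, cs_b: ClusterSet):
    """Pairwise Jaccard matrix between two partitions plus best matches.

    Best match of each cluster of A is its argmax row entry, ties broken by
    the smaller cluster index in B.
    """
    mat = pd.DataFrame(
        [
            [jaccard_index(ca, cb) for cb in cs_b.clusters]
            for ca in cs_a.clusters
        ],
        index=[f"A{i}" for i in range(len(cs_a.clusters))],
        columns=[f"B{j}" for j in range(len(cs_b.clusters))],
    )
    best = {}
    for i in range(len(cs_a.clusters)):
        row = mat.iloc[i].to_numpy()
        j = int(np.argmax(row))  # argmax returns the first (smallest) index on ties
        best[i] = (j, float(row[j]))
    return mat, best


def node_importance(graph: IntegratedGraph) -> pd.DataFrame:
    """Nodes sorted by decreasing degree x betweenness; ties by node id."""
    tab = graph.nodes.copy()
    tab["_id"] = tab.index.astype(str)
    tab = tab.sort_values(["importance", "_id"], ascending=[False, True]).drop(columns="_id")
    return tab
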