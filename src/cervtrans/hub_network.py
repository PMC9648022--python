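"""Node-ranking methods and cross-dataset consensus hub calling.

Nine centrality measures (Betweenness, Bottleneck, Closeness, Degree, EPC,
DMNC, MNC, Radiality, Stress) rank the nodes of each dataset's interaction
network; the union of each method's top-k forms that dataset's candidate
sub-network, and genes whose candidate sets recur in at least ``consensus_min``
datasets are called hubs.

Definitions (n = |V|, d = shortest-path hop distance, sigma_st = number of
shortest s-t paths, sigma_st(v) = those passing through interior node v):

* Degree(v)       = |N(v)|
* Betweenness(v)  = sum over unordered pairs s,t != v of sigma_st(v)/sigma_st
* Stress(v)       = sum over unordered pairs s,t != v of sigma_st(v)
* Closeness(v)    = harmonic form, sum of 1/d(v,u) over reachable u != v
* Radiality(v)    = sum over u != v in v's component C of
                    (diam(C) + 1 - d(v,u)) / (|C| - 1)
* MNC(v)          = size of the largest connected component M of the subgraph
                    induced by the open neighborhood N(v)
* DMNC(v)         = |E(M)| / |V(M)|**eps over that same M (0 if |V(M)| <= 1)
* Bottleneck(v)   = number of roots s whose canonical BFS shortest-path tree
                    places >= fraction * |tree| nodes in v's subtree
* EPC(v)          = mean percolated-cluster size of v over R random edge
                    realizations, divided by n

The BFS tree behind Bottleneck is ambiguous in general; here the parent of a
newly discovered node is its lexicographically smallest neighbor in the
previous BFS layer, which makes scores reproducible and relabeling-invariant
up to name order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import numpy as np

from .io import logger

METHODS = (
    "degree",
    "betweenness",
    "stress",
    "closeness",
    "radiality",
    "mnc",
    "dmnc",
    "bottleneck",
    "epc",
)


@dataclass
class CentralityParams:
    """Tunables of the ranking stage; defaults follow the original plug-in's
    conventions (R = 5000 percolation realizations, DMNC exponent 1.7,
    bottleneck fraction 1/4, top 10 nodes per method, hubs in >= 2 datasets)."""

    epc_realizations: int = 5000
    epc_seed: int = 0
    dmnc_epsilon: float = 1.7
    bottleneck_fraction: float = 0.25
    top_k: int = 10
    consensus_min: int = 2

    def __post_init__(self) -> None:
        if self.epc_realizations < 1:
            raise ValueError("epc_realizations must be >= 1")
        if not 0 < self.bottleneck_fraction < 1:
            raise ValueError("bottleneck_fraction must be in (0, 1)")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")


def _canonical(g: nx.Graph) -> tuple[list, dict, list[list[int]]]:
    nodes = sorted(g.nodes(), key=str)
    index = {v: i for i, v in enumerate(nodes)}
    adj = [sorted(index[u] for u in g.neighbors(v)) for v in nodes]
    return nodes, index, adj


def _bfs_sigma(adj: list[list[int]], s: int, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Hop distances and shortest-path counts from source s."""
    dist = np.full(n, np.inf)
    sigma = np.zeros(n)
    dist[s] = 0
    sigma[s] = 1
    frontier = [s]
    d = 0
    while frontier:
        nxt = []
        for v in frontier:
            for w in adj[v]:
                if dist[w] == np.inf:
                    dist[w] = d + 1
                    nxt.append(w)
                if dist[w] == d + 1:
                    sigma[w] += sigma[v]
        frontier = nxt
        d += 1
    return dist, sigma


def _all_pairs(adj: list[list[int]], n: int) -> tuple[np.ndarray, np.ndarray]:
    D = np.empty((n, n))
    S = np.empty((n, n))
    for s in range(n):
        D[s], S[s] = _bfs_sigma(adj, s, n)
    return D, S


def _path_centralities(D: np.ndarray, S: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Betweenness and Stress over unordered source-target pairs."""
    n = D.shape[0]
    betw = np.zeros(n)
    stress = np.zeros(n)
    triu = np.triu(np.ones((n, n), dtype=bool), k=1)
    finite = np.isfinite(D)
    for v in range(n):
        on_path = finite & (D[:, v][:, None] + D[v, :][None, :] == D)
        mask = on_path & triu
        mask[v, :] = False
        mask[:, v] = False
        if not mask.any():
            continue
        num = S[:, v][:, None] * S[v, :][None, :]
        stress[v] = num[mask].sum()
        betw[v] = (num[mask] / S[mask]).sum()
    return betw, stress


def _components(D: np.ndarray) -> list[np.ndarray]:
    n = D.shape[0]
    seen = np.zeros(n, dtype=bool)
    comps = []
    for v in range(n):
        if not seen[v]:
            members = np.where(np.isfinite(D[v]))[0]
            seen[members] = True
            comps.append(members)
    return comps


def _neighborhood_component(g: nx.Graph, v) -> nx.Graph | None:
    """Largest connected component of the open-neighborhood subgraph; ties are
    broken by edge count, then by smallest member name (deterministic)."""
    sub = g.subgraph(list(g.neighbors(v)))
    if sub.number_of_nodes() == 0:
        return None
    comps = [sub.subgraph(c) for c in nx.connected_components(sub)]
    comps.sort(
        key=lambda c: (-c.number_of_nodes(), -c.number_of_edges(), str(min(c.nodes(), key=str)))
    )
    return comps[0]


def _bottleneck(adj: list[list[int]], n: int, fraction: float) -> np.ndarray:
    score = np.zeros(n)
    for s in range(n):
        parent = np.full(n, -1)
        dist = np.full(n, -1)
        dist[s] = 0
        layer = [s]
        order = [s]
        while layer:
            prev = set(layer)
            nxt = sorted({w for v in layer for w in adj[v] if dist[w] == -1})
            for w in nxt:
                dist[w] = dist[layer[0]] + 1
                parent[w] = min(u for u in adj[w] if u in prev)
            order.extend(nxt)
            layer = nxt
        size = np.zeros(n)
        for v in reversed(order):
            size[v] += 1
            if parent[v] >= 0:
                size[parent[v]] += size[v]
        tree = len(order)
        threshold = fraction * tree
        for v in order:
            if size[v] >= threshold:
                score[v] += 1
    return score


class _UnionFind:
    __slots__ = ("parent", "size")

    def __init__(self, n: int) -> None:
        self.parent = list(range(n))
        self.size = [1] * n

    def find(self, x: int) -> int:
        parent = self.parent
        root = x
        while parent[root] != root:
            root = parent[root]
        while parent[x] != root:
            parent[x], x = root, parent[x]
        return root

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return
        if self.size[ra] < self.size[rb]:
            ra, rb = rb, ra
        self.parent[rb] = ra
        self.size[ra] += self.size[rb]


def _epc(edges: np.ndarray, n: int, realizations: int, rng: np.random.Generator) -> np.ndarray:
    """Monte-Carlo edge-percolated component: each realization draws a global
    threshold t ~ U(0,1) and per-edge uniforms, keeps edges with u < t, and
    credits every node its percolated cluster size."""
    totals = np.zeros(n)
    m = len(edges)
    for _ in range(realizations):
        t = rng.uniform()
        keep = rng.uniform(size=m) < t
        uf = _UnionFind(n)
        for a, b in edges[keep]:
            uf.union(int(a), int(b))
        roots = np.fromiter((uf.find(v) for v in range(n)), dtype=int, count=n)
        totals += np.asarray(uf.size)[roots]
    return totals / (realizations * n)


def centrality(g: nx.Graph, method: str, params: CentralityParams | None = None) -> dict:
    """Score every node of a simple undirected graph by one of the nine methods."""
    params = params or CentralityParams()
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    nodes, index, adj = _canonical(g)
    n = len(nodes)

    if method == "degree":
        return {v: float(g.degree(v)) for v in nodes}
    if method in ("betweenness", "stress", "closeness", "radiality"):
        D, S = _all_pairs(adj, n)
        if method in ("betweenness", "stress"):
            betw, stress = _path_centralities(D, S)
            values = betw if method == "betweenness" else stress
            return {v: float(values[index[v]]) for v in nodes}
        if method == "closeness":
            with np.errstate(divide="ignore"):
                inv = np.where(np.isfinite(D) & (D > 0), 1.0 / np.where(D > 0, D, 1), 0.0)
            return {v: float(inv[index[v]].sum()) for v in nodes}
        # radiality
        scores = np.zeros(n)
        for members in _components(D):
            nc = len(members)
            if nc == 1:
                continue
            sub = D[np.ix_(members, members)]
            diam = sub.max()
            scores[members] = (diam + 1 - sub).sum(axis=1) - (diam + 1)  # drop u == v term
            scores[members] /= nc - 1
        return {v: float(scores[index[v]]) for v in nodes}
    if method in ("mnc", "dmnc"):
        out = {}
        for v in nodes:
            comp = _neighborhood_component(g, v)
            if comp is None or comp.number_of_nodes() <= 1:
                out[v] = 0.0 if method == "dmnc" else float(comp.number_of_nodes() if comp else 0)
            elif method == "mnc":
                out[v] = float(comp.number_of_nodes())
            else:
                out[v] = comp.number_of_edges() / comp.number_of_nodes() ** params.dmnc_epsilon
        return out
    if method == "bottleneck":
        scores = _bottleneck(adj, n, params.bottleneck_fraction)
        return {v: float(scores[index[v]]) for v in nodes}
    # epc
    edges = np.array([[index[a], index[b]] for a, b in g.edges()], dtype=int).reshape(-1, 2)
    rng = np.random.default_rng(params.epc_seed)
    scores = _epc(edges, n, params.epc_realizations, rng)
    return {v: float(scores[index[v]]) for v in nodes}


def top_nodes(scores: Mapping, k: int) -> set:
    """The k highest-scoring nodes, expanded to include every node tied with
    the k-th score; ordering is deterministic by (-score, node name)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    ranked = sorted(scores, key=lambda v: (-scores[v], str(v)))
    if k >= len(ranked):
        return set(ranked)
    kth = scores[ranked[k - 1]]
    return {v for v in ranked if scores[v] >= kth}


def candidate_set(
    g: nx.Graph, params: CentralityParams | None = None
) -> tuple[set, nx.Graph]:
    """Union of each method's top-k nodes and the induced sub-network."""
    params = params or CentralityParams()
    candidates: set = set()
    for method in METHODS:
        candidates |= top_nodes(centrality(g, method, params), params.top_k)
    return candidates, g.subgraph(candidates).copy()


@dataclass
class HubConsensus:
    candidate_sets: dict[str, set]
    membership: dict = field(default_factory=dict)
    hubs: set = field(default_factory=set)


def consensus_hubs(
    candidate_sets: Mapping[str, Iterable], consensus_min: int = 2
) -> HubConsensus:
    """Call hubs as nodes present in >= consensus_min datasets' candidate sets."""
    sets = {k: set(v) for k, v in candidate_sets.items()}
    if len(sets) < consensus_min:
        raise ValueError("consensus_min exceeds the number of datasets")
    membership: dict = {}
    for s in sets.values():
        for v in s:
            membership[v] = membership.get(v, 0) + 1
    hubs = {v for v, c in membership.items() if c >= consensus_min}
    logger.info("consensus: %d candidates, %d hubs (min %d)", len(membership), len(hubs), consensus_min)
    return HubConsensus(candidate_sets=sets, membership=membership, hubs=hubs)
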