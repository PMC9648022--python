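import networkx as nx
import numpy as np
import pytest

from cervtrans import hub_network as hn
from cervtrans.simulate import SimConfig, gen_network

# ---------------------------------------------------------------------------
# brute-force oracles (path enumeration / direct definitions via networkx)
# ---------------------------------------------------------------------------

def oracle_path_counts(g, v):
    """(betweenness, stress) of v by enumerating every shortest path."""
    betw = stress = 0.0
    nodes = sorted(g.nodes(), key=str)
    for i, s in enumerate(nodes):
        for t in nodes[i + 1 :]:
            if s == v or t == v or not nx.has_path(g, s, t):
                continue
            paths = list(nx.all_shortest_paths(g, s, t))
            through = sum(1 for p in paths if v in p[1:-1])
            stress += through
            betw += through / len(paths)
    return betw, stress


def oracle_closeness(g, v):
    lengths = nx.single_source_shortest_path_length(g, v)
    return sum(1.0 / d for u, d in lengths.items() if u != v)


def oracle_radiality(g, v):
    comp = nx.node_connected_component(g, v)
    if len(comp) == 1:
        return 0.0
    sub = g.subgraph(comp)
    diam = nx.diameter(sub)
    lengths = nx.single_source_shortest_path_length(sub, v)
    return sum(diam + 1 - d for u, d in lengths.items() if u != v) / (len(comp) - 1)


def oracle_mnc_dmnc(g, v, eps=1.7):
    sub = g.subgraph(list(g.neighbors(v)))
    if sub.number_of_nodes() == 0:
        return 0.0, 0.0
    comps = sorted(
        (sub.subgraph(c) for c in nx.connected_components(sub)),
        key=lambda c: (-c.number_of_nodes(), -c.number_of_edges(), str(min(c.nodes(), key=str))),
    )
    m = comps[0]
    mnc = m.number_of_nodes()
    dmnc = 0.0 if mnc <= 1 else m.number_of_edges() / mnc**eps
    return float(mnc), dmnc


def oracle_bottleneck(g, fraction=0.25):
    """Re-derive bottleneck scores from explicitly constructed BFS trees."""
    score = {v: 0.0 for v in g.nodes()}
    for root in g.nodes():
        dist = nx.single_source_shortest_path_length(g, root)
        tree = nx.DiGraph()
        tree.add_node(root)
        for v, d in dist.items():
            if v == root:
                continue
            parent = min(
                (u for u in g.neighbors(v) if dist.get(u) == d - 1), key=str
            )
            tree.add_edge(parent, v)
        size = len(tree)
        for v in tree.nodes():
            subtree = 1 + len(nx.descendants(tree, v))
            if subtree >= fraction * size:
                score[v] += 1
    return score


def random_named_graph(rng):
    n = int(rng.integers(2, 11))
    g = nx.gnp_random_graph(n, float(rng.uniform(0.1, 0.8)), seed=int(rng.integers(1 << 30)))
    return nx.relabel_nodes(g, {i: f"n{i:02d}" for i in g.nodes()})


# ---------------------------------------------------------------------------
# closed-form examples
# ---------------------------------------------------------------------------

class TestClosedFormExamples:
    def test_path_interior_vertex(self):
        g = nx.Graph([("a", "b"), ("b", "c")])
        assert hn.centrality(g, "betweenness")["b"] == 1.0
        assert hn.centrality(g, "stress")["b"] == 1.0
        assert hn.centrality(g, "degree")["b"] == 2.0

    def test_triangle_neighborhood_scores(self):
        g = nx.complete_graph(3)
        for v in g:
            assert hn.centrality(g, "mnc")[v] == 2.0
            assert hn.centrality(g, "dmnc")[v] == pytest.approx(1 / 2**1.7)

    def test_single_edge_epc_approaches_three_quarters(self):
        g = nx.Graph([("u", "v")])
        params = hn.CentralityParams(epc_realizations=5000, epc_seed=3)
        # cluster/n is 1 w.p. 1/2 (edge kept) else 1/2; 3 MC SE at R=5000
        se = np.sqrt(0.0625 / 5000)
        assert hn.centrality(g, "epc", params)["u"] == pytest.approx(0.75, abs=3 * se)

    def test_star_center_is_universal_bottleneck(self):
        g = nx.star_graph(4)
        scores = hn.centrality(g, "bottleneck")
        assert scores[0] == 5.0
        assert all(scores[leaf] == 1.0 for leaf in range(1, 5))

    def test_unknown_method_and_empty_graph(self):
        with pytest.raises(ValueError):
            hn.centrality(nx.path_graph(3), "pagerank")
        with pytest.raises(ValueError):
            hn.centrality(nx.Graph(), "degree")


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(20))
    def test_path_based_methods_match_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        g = random_named_graph(rng)
        betw = hn.centrality(g, "betweenness")
        stress = hn.centrality(g, "stress")
        close = hn.centrality(g, "closeness")
        rad = hn.centrality(g, "radiality")
        for v in g.nodes():
            ob, os_ = oracle_path_counts(g, v)
            assert betw[v] == pytest.approx(ob, abs=1e-9)
            assert stress[v] == pytest.approx(os_, abs=1e-9)
            assert close[v] == pytest.approx(oracle_closeness(g, v), abs=1e-9)
            assert rad[v] == pytest.approx(oracle_radiality(g, v), abs=1e-9)

    @pytest.mark.parametrize("seed", range(10))
    def test_neighborhood_and_bottleneck_match_direct_definitions(self, seed):
        rng = np.random.default_rng(100 + seed)
        g = random_named_graph(rng)
        mnc = hn.centrality(g, "mnc")
        dmnc = hn.centrality(g, "dmnc")
        bott = hn.centrality(g, "bottleneck")
        bott_oracle = oracle_bottleneck(g)
        for v in g.nodes():
            om, od = oracle_mnc_dmnc(g, v)
            assert mnc[v] == om
            assert dmnc[v] == pytest.approx(od, abs=1e-9)
            assert bott[v] == bott_oracle[v]


class TestEPCProperties:
    def test_seed_stability_within_mc_error(self):
        g = nx.gnp_random_graph(15, 0.3, seed=9)
        a = hn.centrality(g, "epc", hn.CentralityParams(epc_realizations=5000, epc_seed=1))
        b = hn.centrality(g, "epc", hn.CentralityParams(epc_realizations=5000, epc_seed=2))
        # cluster/n in (0,1] so per-realization variance <= 1/4; pooled 3 SE bound
        tol = 3 * np.sqrt(2 * 0.25 / 5000)
        assert max(abs(a[v] - b[v]) for v in g) < tol

    def test_automorphic_nodes_score_equally(self):
        g = nx.cycle_graph(8)
        scores = hn.centrality(g, "epc", hn.CentralityParams(epc_realizations=5000, epc_seed=5))
        vals = list(scores.values())
        tol = 3 * np.sqrt(2 * 0.25 / 5000)
        assert max(vals) - min(vals) < tol


def test_bottleneck_invariant_under_order_preserving_relabeling():
    g = nx.gnp_random_graph(12, 0.3, seed=4)
    g = nx.relabel_nodes(g, {i: f"n{i:02d}" for i in g.nodes()})
    scores = hn.centrality(g, "bottleneck")
    relabel = {v: v.replace("n", "zz") for v in g.nodes()}  # preserves sort order
    g2 = nx.relabel_nodes(g, relabel)
    scores2 = hn.centrality(g2, "bottleneck")
    assert all(scores[v] == scores2[relabel[v]] for v in g.nodes())


class TestTopNodes:
    def test_exact_k_without_ties(self):
        scores = {"a": 5, "b": 4, "c": 3, "d": 3, "e": 1}
        assert hn.top_nodes(scores, 4) == {"a", "b", "c", "d"}

    def test_tie_expansion_beyond_k(self):
        scores = {"a": 5, "b": 3, "c": 3, "d": 3, "e": 1}
        assert hn.top_nodes(scores, 2) == {"a", "b", "c", "d"}

    def test_k_at_least_n_returns_all(self):
        scores = {"a": 1, "b": 2}
        assert hn.top_nodes(scores, 5) == {"a", "b"}


class TestCandidateSet:
    def test_clique_symmetry_selects_all(self):
        g = nx.complete_graph(5)
        cand, sub = hn.candidate_set(g, hn.CentralityParams(epc_realizations=200, epc_seed=0))
        assert cand == set(g.nodes())
        assert sub.number_of_edges() == 10

    def test_planted_hub_ranks_top_for_path_methods(self, rng):
        hits = 0
        for rep in range(50):
            g = nx.gnp_random_graph(61, 0.03, seed=int(rng.integers(1 << 30)))
            hub = 60
            targets = rng.choice(60, size=30, replace=False)
            g.add_edges_from((hub, int(t)) for t in targets)
            ok = all(
                hub in hn.top_nodes(hn.centrality(g, m), 10)
                for m in ("degree", "betweenness", "closeness")
            )
            hits += ok
        assert hits == 50

    def test_disconnected_cliques_contribute_candidates_from_both(self):
        g = nx.disjoint_union(nx.complete_graph(6), nx.complete_graph(6))
        cand, _ = hn.candidate_set(g, hn.CentralityParams(epc_realizations=200, epc_seed=0))
        assert {v for v in cand if v < 6} and {v for v in cand if v >= 6}


class TestConsensusHubs:
    def test_membership_threshold(self):
        sets = {"d1": {"A", "B"}, "d2": {"A", "C"}, "d3": {"C", "D"}}
        hc = hn.consensus_hubs(sets, 2)
        assert hc.hubs == {"A", "C"}
        assert hc.membership["A"] == 2 and hc.membership["B"] == 1

    def test_strict_all_dataset_reading(self):
        sets = {"d1": {"A", "B"}, "d2": {"A", "C"}, "d3": {"A", "D"}}
        assert hn.consensus_hubs(sets, 3).hubs == {"A"}

    def test_min_exceeding_datasets_is_error(self):
        with pytest.raises(ValueError):
            hn.consensus_hubs({"d1": {"A"}}, 2)


def test_planted_hub_consensus_recovery_smoke():
    """Light version of the consensus-recovery property (full run lives in the
    acceptance suite): 10 replicates, all planted hubs found, <=1 false."""
    rng = np.random.default_rng(21)
    cfg = SimConfig(seed=21)
    params = hn.CentralityParams(epc_realizations=300, epc_seed=11)
    for _ in range(10):
        sets = {}
        for d in range(3):
            g, hubs = gen_network(cfg, rng)
            sets[f"d{d}"], _ = hn.candidate_set(g, params)
        hc = hn.consensus_hubs(sets, 2)
        assert set(hubs) <= hc.hubs
        assert len(hc.hubs - set(hubs)) <= 1
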