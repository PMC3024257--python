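import itertools
import math

import networkx as nx
import numpy as np
import pytest

from isamod import network_analysis as na


def net_from(edges, vertices=None):
    return na.GeneNetwork.from_edges(edges, vertices)


class TestGeneNetwork:
    def test_self_loop_rejected(self):
        g = nx.Graph()
        g.add_edge("a", "a")
        with pytest.raises(na.NetworkError):
            na.GeneNetwork(g)

    def test_evidence_range_enforced(self):
        with pytest.raises(na.NetworkError):
            net_from([("a", "b", 1.5)])

    def test_largest_component(self):
        net = net_from([("a", "b", 0.5), ("b", "c", 0.5), ("x", "y", 0.5)])
        comp = net.largest_component()
        assert set(comp.vertices) == {"a", "b", "c"}


class TestExtractSubnetwork:
    def test_identity_extraction(self):
        net = net_from([("a", "b", 0.5), ("b", "c", 0.9)])
        sub = na.extract_subnetwork(net, net.vertices, 0.0)
        assert sub.n_edges == 2

    def test_min_evidence_one_removes_all_edges(self):
        net = net_from([("a", "b", 0.5), ("b", "c", 0.9)])
        sub = na.extract_subnetwork(net, net.vertices, 1.0)
        assert sub.n_edges == 0

    def test_toy_threshold_case(self):
        net = net_from(
            [
                ("a", "b", 0.9),
                ("b", "c", 0.4),
                ("a", "c", 0.2),
                ("c", "d", 0.8),
                ("d", "e", 0.9),
            ]
        )
        sub = na.extract_subnetwork(net, {"a", "b", "c"}, 0.3)
        assert set(map(frozenset, sub.graph.edges)) == {
            frozenset({"a", "b"}),
            frozenset({"b", "c"}),
        }


class TestTotalEvidence:
    def test_empty_is_zero(self):
        assert na.total_evidence(net_from([], vertices=["a"])) == 0.0

    def test_single_edge(self):
        assert na.total_evidence(net_from([("a", "b", 0.7)])) == pytest.approx(0.7)

    def test_triangle_sum(self):
        net = net_from([("a", "b", 0.3), ("b", "c", 0.4), ("a", "c", 0.5)])
        assert na.total_evidence(net) == pytest.approx(1.2)


class TestRandomSubnetworkNull:
    def test_full_network_draws(self):
        net = net_from([("a", "b", 0.5), ("b", "c", 0.5)])
        p, nulls = na.random_subnetwork_null(
            net, 3, 10, na.total_evidence(net), rng_seed=0
        )
        assert p == pytest.approx(1.0)
        assert np.allclose(nulls, 1.0)

    def test_infinite_observed(self):
        net = net_from([("a", "b", 0.5), ("b", "c", 0.5)])
        p, _ = na.random_subnetwork_null(net, 2, 99, math.inf, rng_seed=0)
        assert p == pytest.approx(1 / 100)

    def test_planted_dense_module_is_significant(self):
        rng = np.random.default_rng(0)
        g = nx.Graph()
        vertices = [f"v{i}" for i in range(60)]
        g.add_nodes_from(vertices)
        module = vertices[:10]
        for u, v in itertools.combinations(vertices, 2):
            within = u in module[:10] and v in module[:10]
            p_edge = 0.8 if within else 0.05
            if rng.random() < p_edge:
                g.add_edge(u, v, evidence=0.5)
        net = na.GeneNetwork(g)
        sub = na.extract_subnetwork(net, module)
        observed = na.total_evidence(sub)
        p, _ = na.random_subnetwork_null(net, 10, 1000, observed, rng_seed=1)
        assert p <= 0.01

    def test_k_too_large_is_error(self):
        net = net_from([("a", "b", 0.5)])
        with pytest.raises(na.NetworkError):
            na.random_subnetwork_null(net, 5, 10, 0.0)

    def test_deterministic(self):
        net = net_from([("a", "b", 0.5), ("b", "c", 0.4), ("c", "d", 0.9)])
        p1, n1 = na.random_subnetwork_null(net, 2, 50, 0.5, rng_seed=9)
        p2, n2 = na.random_subnetwork_null(net, 2, 50, 0.5, rng_seed=9)
        assert p1 == p2
        assert np.allclose(n1, n2)


class TestPagerank:
    def test_two_vertices_symmetric(self):
        net = net_from([("a", "b", 0.5)])
        pr = na.pagerank(net)
        assert pr["a"] == pytest.approx(0.5)
        assert pr["b"] == pytest.approx(0.5)

    def test_star_closed_form(self):
        net = net_from([("hub", "l1", 1.0), ("hub", "l2", 1.0), ("hub", "l3", 1.0)])
        pr = na.pagerank(net, damping=0.85)
        assert pr["hub"] == pytest.approx(0.4797, abs=1e-4)
        for leaf in ("l1", "l2", "l3"):
            assert pr[leaf] == pytest.approx(0.1734, abs=1e-4)

    def test_sums_to_one_with_isolates(self):
        net = net_from([("a", "b", 0.5)], vertices=["a", "b", "iso"])
        pr = na.pagerank(net)
        assert sum(pr.values()) == pytest.approx(1.0, abs=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_linear_solve_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 11))
        g = nx.gnp_random_graph(n, 0.4, seed=seed)
        net = na.GeneNetwork(g)
        d = 0.85
        pr = na.pagerank(net, damping=d, tol=1e-14)
        # oracle: solve (I - d M) x = teleport, M includes dangling spread
        A = nx.to_numpy_array(g)
        deg = A.sum(axis=1)
        M = np.zeros((n, n))
        for j in range(n):
            if deg[j] > 0:
                M[:, j] = A[:, j] / deg[j]
            else:
                M[:, j] = 1.0 / n
        x = np.linalg.solve(np.eye(n) - d * M, np.full(n, (1 - d) / n))
        x = x / x.sum()
        ours = np.array([pr[v] for v in g.nodes])
        assert np.allclose(ours, x, atol=1e-8)


class TestDegreeCentralityCompare:
    def _hand_network(self):
        # sub = {a,b,c} with degrees 3; rest = {d,e,f} with degree 1
        edges = [("a", "b"), ("a", "c"), ("b", "c"), ("a", "d"), ("b", "e"), ("c", "f")]
        return net_from([(u, v, 0.5) for u, v in edges])

    def test_exact_enumeration_hand_case(self):
        full = self._hand_network()
        sub = na.extract_subnetwork(full, {"a", "b", "c"})
        p, dists = na.degree_centrality_compare(sub, full, "degree")
        # all sub degrees strictly above the rest: one-sided 1/C(6,3)
        assert p == pytest.approx(2 / 20)

    def test_sub_equal_full_is_error(self):
        full = self._hand_network()
        with pytest.raises(na.NetworkError):
            na.degree_centrality_compare(full, full)

    def test_calibration_identical_distributions(self):
        pvals = []
        for seed in range(40):
            g = nx.gnp_random_graph(60, 0.15, seed=seed)
            net = na.GeneNetwork(g)
            rng = np.random.default_rng(seed)
            chosen = rng.choice(net.vertices, size=20, replace=False)
            sub = na.extract_subnetwork(net, chosen)
            p, _ = na.degree_centrality_compare(sub, net, "degree")
            pvals.append(p)
        # random vertex subsets: p should not concentrate near 0
        assert np.mean(np.array(pvals) < 0.05) <= 0.2

    def test_pagerank_measure(self):
        full = self._hand_network()
        sub = na.extract_subnetwork(full, {"a", "b", "c"})
        p, _ = na.degree_centrality_compare(sub, full, "pagerank")
        assert p == pytest.approx(2 / 20)


def all_dendrograms(leaves):
    """Yield every labelled binary dendrogram shape as nested tuples."""
    if len(leaves) == 1:
        yield leaves[0]
        return
    first, rest = leaves[0], leaves[1:]
    for size in range(0, len(rest)):
        for extra in itertools.combinations(rest, size):
            left = [first, *extra]
            right = [x for x in rest if x not in extra]
            if not right:
                continue
            for lt in all_dendrograms(left):
                for rt in all_dendrograms(right):
                    yield (lt, rt)


def tree_to_model(tree, leaves):
    left, right = [], []

    def build(t):
        if not isinstance(t, tuple):
            return -(leaves.index(t) + 1)
        l = build(t[0])
        r = build(t[1])
        left.append(l)
        right.append(r)
        return len(left) - 1

    root = build(tree)
    return na.DendrogramModel(leaves, left, right, root)


class TestHrgLoglik:
    def test_triangle_is_zero(self):
        net = na.GeneNetwork(nx.complete_graph(3))
        model = na.random_dendrogram(net.vertices, np.random.default_rng(0))
        assert na.hrg_loglik(net, model) == pytest.approx(0.0)

    def test_path_hand_computation(self):
        net = net_from([("a", "b", 1.0), ("b", "c", 1.0)])
        model = tree_to_model(("a", ("b", "c")), ["a", "b", "c"])
        assert na.hrg_loglik(net, model) == pytest.approx(-2 * math.log(2))

    def test_loglik_nonpositive(self):
        for seed in range(5):
            g = nx.gnp_random_graph(8, 0.4, seed=seed)
            if not nx.is_connected(g):
                continue
            net = na.GeneNetwork(g)
            model = na.random_dendrogram(net.vertices, np.random.default_rng(seed))
            assert na.hrg_loglik(net, model) <= 1e-12

    def test_wrong_leaf_set_is_error(self):
        net = net_from([("a", "b", 1.0), ("b", "c", 1.0)])
        model = tree_to_model(("a", ("b", "x")), ["a", "b", "x"])
        with pytest.raises(na.NetworkError):
            na.hrg_loglik(net, model)


class TestFitHrg:
    @pytest.mark.parametrize(
        "edges",
        [
            [("a", "b"), ("b", "c"), ("c", "d")],
            [("a", "b"), ("b", "c"), ("c", "d"), ("a", "c")],
            [("a", "b"), ("b", "c"), ("c", "d"), ("d", "a")],
        ],
    )
    def test_exhaustive_enumeration_four_vertices(self, edges):
        net = net_from([(u, v, 1.0) for u, v in edges])
        leaves = sorted(net.vertices)
        trees = list(all_dendrograms(leaves))
        assert len(trees) == 15  # (2n-3)!! labelled shapes for n=4
        best_enum = max(na.hrg_loglik(net, tree_to_model(t, leaves)) for t in trees)
        _, best_fit = na.fit_hrg(net, n_steps=2000, rng_seed=0)
        assert best_fit == pytest.approx(best_enum, abs=1e-9)

    def test_clique_pair_beats_random_dendrograms(self):
        g = nx.disjoint_union(nx.complete_graph(5), nx.complete_graph(5))
        g.add_edge(0, 5)
        net = na.GeneNetwork(g)
        model, best = na.fit_hrg(net, n_steps=5000, rng_seed=0)
        rng = np.random.default_rng(1)
        adj = na._adjacency_masks(net, model.leaves)
        for _ in range(100):
            rand = na.random_dendrogram(model.leaves, rng)
            rand.compute_edge_counts(adj)
            assert best >= rand.loglik() - 1e-9

    def test_best_loglik_nondecreasing_in_steps(self):
        g = nx.disjoint_union(nx.complete_graph(4), nx.complete_graph(4))
        g.add_edge(0, 4)
        net = na.GeneNetwork(g)
        previous = -math.inf
        for steps in (1, 100, 10000):
            _, best = na.fit_hrg(net, n_steps=steps, rng_seed=3)
            assert best >= previous - 1e-12
            previous = best

    def test_disconnected_is_error(self):
        net = net_from([("a", "b", 1.0), ("c", "d", 1.0)])
        with pytest.raises(na.NetworkError):
            na.fit_hrg(net, n_steps=10)

    def test_dendrogram_pair_partition_invariant(self):
        g = nx.gnp_random_graph(12, 0.3, seed=2)
        net = na.GeneNetwork(g).largest_component()
        model, _ = na.fit_hrg(net, n_steps=500, rng_seed=0)
        n = len(model.leaves)
        total_pairs = sum(L * R for L, R, *_ in model.table())
        assert total_pairs == n * (n - 1) // 2
        for L, R, E, p in model.table():
            assert 0 <= E <= L * R
            assert 0 <= p <= 1


class TestRewire:
    def test_four_cycle_stays_two_regular(self):
        net = net_from([("a", "b", 0.5), ("b", "c", 0.5), ("c", "d", 0.5), ("d", "a", 0.5)])
        out = na.rewire_degree_preserving(net, 100, rng_seed=0)
        assert sorted(d for _, d in out.graph.degree) == [2, 2, 2, 2]

    @pytest.mark.parametrize("seed", range(5))
    def test_degree_sequence_preserved(self, seed):
        g = nx.gnp_random_graph(20, 0.25, seed=seed)
        net = na.GeneNetwork(g)
        out = na.rewire_degree_preserving(net, 200, rng_seed=seed)
        assert dict(out.graph.degree) == dict(net.graph.degree)
        assert out.n_edges == net.n_edges

    def test_small_state_space_enumeration(self):
        # triangle + isolated edge: the only simple graphs with per-vertex
        # degrees (a,b,c)=2,(d,e)=1 are the triangle+edge and the 5-paths
        # with d,e as endpoints
        net = net_from(
            [("a", "b", 0.5), ("b", "c", 0.5), ("a", "c", 0.5), ("d", "e", 0.5)]
        )
        valid = set()
        base_degrees = {"a": 2, "b": 2, "c": 2, "d": 1, "e": 1}
        for edges in itertools.combinations(
            itertools.combinations(sorted(base_degrees), 2), 4
        ):
            g = nx.Graph(edges)
            if dict(g.degree) == base_degrees:
                valid.add(frozenset(frozenset(e) for e in g.edges))
        seen = set()
        for seed in range(50):
            out = na.rewire_degree_preserving(net, 30, rng_seed=seed)
            seen.add(frozenset(frozenset(e) for e in out.graph.edges))
        assert seen <= valid

    def test_evidence_multiset_preserved(self):
        net = net_from([("a", "b", 0.1), ("b", "c", 0.2), ("c", "d", 0.3), ("d", "a", 0.4)])
        out = na.rewire_degree_preserving(net, 50, rng_seed=1)
        before = sorted(d["evidence"] for *_, d in net.graph.edges(data=True))
        after = sorted(d["evidence"] for *_, d in out.graph.edges(data=True))
        assert before == pytest.approx(after)


def block_graph(rng, n_blocks=3, size=10, p_in=0.8, p_out=0.03):
    g = nx.Graph()
    nodes = list(range(n_blocks * size))
    g.add_nodes_from(nodes)
    for i in nodes:
        for j in nodes:
            if i < j and rng.random() < (p_in if i // size == j // size else p_out):
                g.add_edge(i, j, evidence=0.5)
    return na.GeneNetwork(g)


class TestHierarchySignificance:
    def test_hierarchical_graph_detected(self):
        net = block_graph(np.random.default_rng(100)).largest_component()
        _, _, p = na.hierarchy_significance(net, n_random=50, n_steps=2000, rng_seed=0)
        assert p <= 0.05

    def test_random_graph_not_detected(self):
        net = na.GeneNetwork(nx.gnp_random_graph(30, 0.2, seed=4)).largest_component()
        _, _, p = na.hierarchy_significance(net, n_random=50, n_steps=2000, rng_seed=0)
        assert p >= 0.05

    def test_single_null_bounds(self):
        net = block_graph(np.random.default_rng(1), n_blocks=2, size=5).largest_component()
        _, nulls, p = na.hierarchy_significance(net, n_random=1, n_steps=200, rng_seed=0)
        assert p in (0.5, 1.0)
        assert len(nulls) == 1

    def test_too_small_is_error(self):
        net = net_from([("a", "b", 1.0), ("b", "c", 1.0)])
        with pytest.raises(na.NetworkError):
            na.hierarchy_significance(net, n_random=1, n_steps=10)
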