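"""Co-occurrence network construction, modules, topology and roles."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from phyllonet.community import OtuTable
from phyllonet.network import (
    CooccurrenceNetwork,
    abundance_filter,
    build_network,
    classify_roles,
    compare_region_topologies,
    degree_distribution,
    detect_modules,
    erdos_renyi_baseline,
    induced_subnetwork,
    spearman_matrix,
    topology_metrics,
    zi_pi,
)

from oracles import (
    modularity_bruteforce,
    spearman_bruteforce,
    topology_bruteforce,
    zi_pi_bruteforce,
)


def net_from_edges(edges, nodes=None, modules=None):
    g = nx.Graph()
    if nodes:
        g.add_nodes_from(nodes)
    g.add_edges_from(edges)
    return CooccurrenceNetwork(g, modules=modules)


def table_from(counts):
    counts = np.asarray(counts)
    return OtuTable(
        pd.DataFrame(
            counts,
            index=[f"s{i}" for i in range(counts.shape[0])],
            columns=[f"o{j}" for j in range(counts.shape[1])],
        )
    )


class TestAbundanceFilter:
    def test_rule_boundaries(self):
        # totals: 9, 11, 99980 of 100000 reads -> 0.009 %, 0.011 % overall
        t = table_from([[9, 11, 99_980]])
        kept = abundance_filter(t, 0.0001)
        assert kept.otus == ["o1", "o2"]

    def test_zero_threshold_identity(self):
        t = table_from([[3, 4], [5, 6]])
        assert abundance_filter(t, 0.0).otus == t.otus

    def test_toy_hand_tally(self):
        t = table_from([[5, 0, 100], [5, 1, 889]])  # total 1000
        kept = abundance_filter(t, 0.005)
        assert kept.otus == ["o0", "o2"]  # 10/1000 and 989/1000 pass, 1/1000 fails


class TestSpearmanMatrix:
    def test_monotone_and_antimonotone_pairs(self):
        x = np.arange(10)
        counts = np.column_stack([x, x**2 + 1, 50 - 3 * x]).astype(int)
        rho, p = spearman_matrix(table_from(counts))
        assert rho.iloc[0, 1] == pytest.approx(1.0)
        assert rho.iloc[0, 2] == pytest.approx(-1.0)
        np.testing.assert_allclose(np.diag(rho), 1.0)

    def test_tied_vectors_match_midrank_oracle(self):
        counts = np.array(
            [[3, 1], [3, 5], [7, 5], [2, 5], [2, 8], [9, 8]]
        )
        rho, _ = spearman_matrix(table_from(counts))
        assert rho.iloc[0, 1] == pytest.approx(
            spearman_bruteforce(counts[:, 0], counts[:, 1]), abs=1e-12
        )

    def test_oracle_equivalence_on_random_tied_instances(self):
        for seed in range(100):
            r = np.random.default_rng(seed)
            counts = r.integers(0, 5, size=(8, 3))
            if (np.ptp(counts, axis=0) == 0).any():
                continue
            rho, _ = spearman_matrix(table_from(counts))
            for a, b in itertools.combinations(range(3), 2):
                assert rho.iloc[a, b] == pytest.approx(
                    spearman_bruteforce(counts[:, a], counts[:, b]), abs=1e-12
                )

    def test_constant_otu_recorded_as_zero(self):
        counts = np.column_stack([np.arange(6), np.full(6, 4)])
        rho, p = spearman_matrix(table_from(counts))
        assert rho.iloc[0, 1] == 0.0
        assert p.iloc[0, 1] == 1.0

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            spearman_matrix(table_from([[1, 2], [3, 4], [5, 6]]))


class TestBuildNetwork:
    def test_no_pair_passes_gives_empty_network(self):
        otus = ["a", "b"]
        rho = pd.DataFrame([[1.0, 0.3], [0.3, 1.0]], index=otus, columns=otus)
        p = pd.DataFrame([[0.0, 0.5], [0.5, 0.0]], index=otus, columns=otus)
        net = build_network(rho, p)
        assert net.n_edges == 0 and net.n_nodes == 0

    def test_default_thresholds(self):
        import inspect

        sig = inspect.signature(build_network)
        assert sig.parameters["rho_min"].default == 0.6
        assert sig.parameters["alpha"].default == 0.05

    def test_planted_block_recovered(self):
        # latent-factor simulation: 10 co-varying OTUs + 30 noise, 60 samples
        rng = np.random.default_rng(0)
        n = 60
        factor = rng.normal(size=n)
        block = np.sqrt(0.8) * factor[:, None] + np.sqrt(0.2) * rng.normal(size=(n, 10))
        noise = rng.normal(size=(n, 30))
        counts = np.rint(np.exp(2.2 + np.column_stack([block, noise]))).astype(int)
        t = table_from(counts)
        rho, p = spearman_matrix(t)
        net = build_network(rho, p)
        block_ids = {f"o{j}" for j in range(10)}
        block_pairs = sum(
            1
            for a, b in itertools.combinations(sorted(block_ids), 2)
            if net.graph.has_edge(a, b)
        )
        cross = sum(
            1 for a, b in net.graph.edges
            if (a in block_ids) != (b in block_ids)
        )
        assert block_pairs >= 0.8 * 45
        assert cross < 0.05 * 10 * 30

    def test_edge_attributes_and_sign(self):
        otus = ["a", "b", "c"]
        rho = pd.DataFrame(
            [[1, 0.9, -0.9], [0.9, 1, 0.1], [-0.9, 0.1, 1]],
            index=otus, columns=otus, dtype=float,
        )
        p = pd.DataFrame(1e-9 * np.ones((3, 3)), index=otus, columns=otus)
        net = build_network(rho, p)
        assert net.graph.edges["a", "b"]["sign"] == "positive"
        assert net.graph.edges["a", "c"]["sign"] == "negative"
        assert net.positive_edge_fraction() == pytest.approx(0.5)


class TestInducedSubnetwork:
    def test_full_presence_identity(self):
        net = net_from_edges([("a", "b"), ("b", "c")], modules={"a": 0, "b": 0, "c": 1})
        detect_modules(net, seed=0)
        sub = induced_subnetwork(net, ["a", "b", "c"])
        assert set(sub.graph.edges) == set(net.graph.edges)

    def test_missing_endpoints_remove_edges(self):
        net = net_from_edges([("a", "b"), ("c", "d")])
        sub = induced_subnetwork(net, ["a", "c"])
        assert sub.n_edges == 0 and sub.n_nodes == 2

    def test_hand_derived_induced_set_and_module_inheritance(self):
        edges = [("a", "b"), ("a", "c"), ("c", "d"), ("d", "e"), ("b", "e")]
        net = net_from_edges(edges)
        detect_modules(net, seed=0)
        with pytest.warns(UserWarning):
            sub = induced_subnetwork(net, ["a", "c", "d", "zz"])
        assert set(sub.graph.edges) == {("a", "c"), ("c", "d")}
        assert sub.modules == {k: net.modules[k] for k in ["a", "c", "d"]}

    def test_metrics_dominated_by_parent(self, rng):
        g = nx.gnm_random_graph(20, 40, seed=1)
        net = CooccurrenceNetwork(nx.relabel_nodes(g, str))
        for seed in range(10):
            present = [str(v) for v in rng.choice(20, size=12, replace=False)]
            sub = induced_subnetwork(net, present)
            assert sub.n_nodes <= net.n_nodes
            assert sub.n_edges <= net.n_edges


class TestModules:
    def test_two_disconnected_triangles(self):
        edges = [("a", "b"), ("b", "c"), ("a", "c"),
                 ("x", "y"), ("y", "z"), ("x", "z")]
        net = net_from_edges(edges)
        mods, q = detect_modules(net, seed=0)
        assert q == pytest.approx(0.5)
        assert len({mods["a"], mods["x"]}) == 2
        assert mods["a"] == mods["b"] == mods["c"]

    def test_complete_graph_single_module_zero_q(self):
        edges = list(itertools.combinations("abcde", 2))
        net = net_from_edges(edges)
        mods, q = detect_modules(net, seed=0)
        assert len(set(mods.values())) == 1
        assert q == pytest.approx(0.0)

    def test_two_cliques_with_bridge_recovered(self):
        c1 = [f"a{i}" for i in range(5)]
        c2 = [f"b{i}" for i in range(5)]
        edges = list(itertools.combinations(c1, 2)) + list(
            itertools.combinations(c2, 2)
        ) + [(c1[0], c2[0])]
        net = net_from_edges(edges)
        mods, q = detect_modules(net, seed=0)
        assert len({mods[v] for v in c1}) == 1
        assert len({mods[v] for v in c2}) == 1
        assert mods[c1[0]] != mods[c2[0]]
        # modularity agrees with the Newman-Girvan definition
        assert q == pytest.approx(
            modularity_bruteforce(edges, c1 + c2, mods), abs=1e-12
        )

    def test_edgeless_graph_singletons(self):
        net = net_from_edges([], nodes=["a", "b"])
        mods, q = detect_modules(net, seed=0)
        assert q == 0.0
        assert len(set(mods.values())) == 2


class TestTopologyMetrics:
    def test_star_centralizations_are_one(self):
        edges = [("hub", f"v{i}") for i in range(9)]
        m = topology_metrics(net_from_edges(edges), seed=0)
        assert m.degree_centralization == pytest.approx(1.0)
        assert m.closeness_centralization == pytest.approx(1.0)
        assert m.n_nodes == 10 and m.n_edges == 9

    def test_complete_graph_zero_centralization(self):
        edges = list(itertools.combinations(range(6), 2))
        m = topology_metrics(net_from_edges(edges), seed=0)
        assert m.degree_centralization == 0.0
        assert m.closeness_centralization == 0.0
        assert m.avg_degree == pytest.approx(5.0)

    def test_path_graph_hand_values(self):
        edges = [("a", "b"), ("b", "c"), ("c", "d")]
        m = topology_metrics(net_from_edges(edges), seed=0)
        oracle = topology_bruteforce(edges, ["a", "b", "c", "d"])
        assert m.avg_degree == pytest.approx(oracle["avg_degree"])
        assert m.degree_centralization == pytest.approx(
            oracle["degree_centralization"]
        )
        assert m.closeness_centralization == pytest.approx(
            oracle["closeness_centralization"]
        )
        # explicit hand numbers: degrees 1,2,2,1; closeness 1/2, 3/5, 3/5, 1/2
        assert m.degree_centralization == pytest.approx((1 + 0 + 0 + 1) / 6)

    def test_oracle_equivalence_on_random_graphs(self):
        for seed in range(100):
            r = np.random.default_rng(seed)
            n = int(r.integers(3, 15))
            mmax = n * (n - 1) // 2
            medges = int(r.integers(1, mmax + 1))
            g = nx.gnm_random_graph(n, medges, seed=seed)
            g = nx.relabel_nodes(g, str)
            got = topology_metrics(CooccurrenceNetwork(g.copy()), seed=0)
            oracle = topology_bruteforce([tuple(e) for e in g.edges], list(g.nodes))
            for key in ("n_nodes", "n_edges", "avg_degree",
                        "degree_centralization", "closeness_centralization"):
                assert getattr(got, key) == pytest.approx(oracle[key], abs=1e-12)

    def test_tiny_graphs_have_zero_centralization(self):
        m = topology_metrics(net_from_edges([("a", "b")]), seed=0)
        assert m.degree_centralization == 0.0
        assert m.closeness_centralization == 0.0


class TestErdosRenyiBaseline:
    def test_replicates_have_exact_counts_and_mean_degree(self):
        reps, summary = erdos_renyi_baseline(30, 45, n_reps=20, seed=0)
        assert all(m.n_nodes == 30 and m.n_edges == 45 for m in reps)
        assert summary.loc["avg_degree", "mean"] == pytest.approx(3.0)

    def test_random_graphs_less_modular_than_planted_cliques(self):
        c1 = [f"a{i}" for i in range(6)]
        c2 = [f"b{i}" for i in range(6)]
        edges = list(itertools.combinations(c1, 2)) + list(
            itertools.combinations(c2, 2)
        ) + [(c1[0], c2[0])]
        planted = topology_metrics(net_from_edges(edges), seed=0)
        reps, summary = erdos_renyi_baseline(12, len(edges), n_reps=30, seed=1)
        assert summary.loc["modularity", "mean"] < planted.modularity

    def test_infeasible_edge_count_rejected(self):
        with pytest.raises(ValueError):
            erdos_renyi_baseline(4, 7)


class TestZiPi:
    def test_all_links_inside_module_pi_zero(self):
        net = net_from_edges(
            [("a", "b"), ("b", "c")], modules={"a": 0, "b": 0, "c": 0}
        )
        t = zi_pi(net)
        assert (t["pi"] == 0.0).all()

    def test_even_split_across_two_modules_pi_half(self):
        net = net_from_edges(
            [("x", "a"), ("x", "b")], modules={"x": 0, "a": 0, "b": 1}
        )
        t = zi_pi(net)
        assert t.loc["x", "pi"] == pytest.approx(0.5)

    def test_equal_within_degrees_give_zero_zi(self):
        edges = list(itertools.combinations("abcd", 2))
        net = net_from_edges(edges, modules={v: 0 for v in "abcd"})
        assert (zi_pi(net)["zi"] == 0.0).all()

    def test_bruteforce_agreement_on_random_graphs(self):
        for seed in range(100):
            r = np.random.default_rng(seed)
            n = int(r.integers(4, 40))
            p_edge = 0.15
            g = nx.gnp_random_graph(n, p_edge, seed=seed)
            g = nx.relabel_nodes(g, str)
            modules = {v: int(r.integers(0, 3)) for v in g.nodes}
            net = CooccurrenceNetwork(g, modules=modules)
            ours = zi_pi(net)
            oracle = zi_pi_bruteforce([tuple(e) for e in g.edges], modules)
            for v in g.nodes:
                zi, pi = oracle[v]
                assert ours.loc[v, "zi"] == pytest.approx(zi, abs=1e-12)
                assert ours.loc[v, "pi"] == pytest.approx(pi, abs=1e-12)

    def test_requires_modules(self):
        with pytest.raises(ValueError):
            zi_pi(net_from_edges([("a", "b")]))


class TestRoles:
    @pytest.mark.parametrize(
        "zi,pi,role",
        [
            (3.0, 0.10, "module hub"),
            (1.0, 0.70, "connector"),
            (2.6, 0.70, "network hub"),
            (1.0, 0.10, "peripheral"),
            (2.5, 0.62, "peripheral"),  # exact thresholds fall to peripheral
        ],
    )
    def test_threshold_classification(self, zi, pi, role):
        df = pd.DataFrame({"zi": [zi], "pi": [pi]}, index=["n1"])
        out = classify_roles(df)
        assert out.loc["n1", "role"] == role
        assert out.loc["n1", "keystone"] == (role != "peripheral")

    def test_roles_partition_all_nodes(self, rng):
        df = pd.DataFrame(
            {"zi": rng.normal(0, 2, 200), "pi": rng.uniform(0, 1, 200)}
        )
        out = classify_roles(df)
        assert out["role"].isin(
            ["peripheral", "connector", "module hub", "network hub"]
        ).all()

    def test_removing_connectors_disconnects_module_toy(self):
        # Pi > 0.62 needs links spread over >= 3 modules, so the toy uses
        # three cliques joined only through one bridge node
        cliques = [[f"{c}{i}" for i in range(4)] for c in "abc"]
        bridge = "m"
        edges = [e for cl in cliques for e in itertools.combinations(cl, 2)]
        edges += [(bridge, cl[0]) for cl in cliques]
        modules = {v: k for k, cl in enumerate(cliques) for v in cl}
        modules[bridge] = 0
        net = net_from_edges(edges, modules=modules)
        topo = classify_roles(zi_pi(net))
        connectors = list(topo.index[topo["role"] == "connector"])
        assert bridge in connectors
        g = net.graph.copy()
        g.remove_nodes_from(connectors)
        comps = [set(c) for c in nx.connected_components(g)]
        for cl in cliques:
            assert any(set(cl) <= c and len(c) == len(cl) for c in comps)


class TestRegionComparison:
    def test_identical_vectors_p_one(self):
        pm = pd.DataFrame(
            {"n_edges": [5, 5, 5, 5]}, index=["a", "b", "c", "d"]
        )
        regions = pd.Series(["X", "X", "Y", "Y"], index=pm.index)
        out = compare_region_topologies(pm, regions)
        assert out.loc["n_edges", "p"] == 1.0

    def test_disjoint_ranges_reach_design_minimum_p(self):
        pm = pd.DataFrame({"m": [1, 2, 3, 10, 11, 12]},
                          index=[f"s{i}" for i in range(6)])
        regions = pd.Series(["X"] * 3 + ["Y"] * 3, index=pm.index)
        out = compare_region_topologies(pm, regions)
        assert out.loc["m", "p"] == pytest.approx(0.1)  # 2/C(6,3)

    def test_requires_two_regions(self):
        pm = pd.DataFrame({"m": [1, 2]}, index=["a", "b"])
        with pytest.raises(ValueError):
            compare_region_topologies(pm, pd.Series(["X", "X"], index=pm.index))


class TestDegreeDistribution:
    def test_regular_graph_single_bin(self):
        edges = [("a", "b"), ("b", "c"), ("c", "a")]
        out = degree_distribution(net_from_edges(edges))
        assert out["slope"] is None
        assert list(out["histogram"].index) == [2]

    def test_star_two_bins_negative_slope(self):
        edges = [("hub", f"v{i}") for i in range(9)]
        out = degree_distribution(net_from_edges(edges))
        assert out["slope"] < 0
        assert len(out["histogram"]) == 2

    def test_preferential_attachment_scale_free_slope(self):
        g = nx.barabasi_albert_graph(500, 2, seed=0)
        out = degree_distribution(CooccurrenceNetwork(nx.relabel_nodes(g, str)))
        assert -3.5 <= out["slope"] <= -1.5

    def test_edgeless_rejected(self):
        with pytest.raises(ValueError):
            degree_distribution(net_from_edges([], nodes=["a"]))
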