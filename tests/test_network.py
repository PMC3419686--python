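"""Spearman correlation networks and the Louvain modularity optimizer."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gutnet import network as net_mod
from gutnet.exceptions import GutnetError, UndefinedStatisticError
from gutnet.network import (
    build_network,
    correlation_matrix,
    dominant_subnetwork,
    louvain,
    modularity,
    spearman,
    trait_network,
)
from gutnet.simulate import null_profiles_and_traits, planted_correlation_profiles


# --------------------------------------------------------------------------
# oracles


def exhaustive_best_modularity(graph: nx.Graph) -> float:
    """Best Newman-Girvan modularity over all partitions (n <= 8)."""
    from sympy.utilities.iterables import multiset_partitions

    nodes = list(graph.nodes)
    best = -1.0
    for parts in multiset_partitions(list(range(len(nodes)))):
        partition = {}
        for c, block in enumerate(parts):
            for i in block:
                partition[nodes[i]] = c
        best = max(best, modularity(graph, partition))
    return best


def permutation_p_spearman(x, y, n_perm=100_000, seed=0):
    rng = np.random.default_rng(seed)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    obs = abs(np.corrcoef(rx, ry)[0, 1])
    n = len(ry)
    u = rng.random((n_perm, n))
    perms = np.argsort(u, axis=1)
    ry_perm = ry[perms]
    rx_c = rx - rx.mean()
    ry_c = ry_perm - ry_perm.mean(axis=1, keepdims=True)
    num = ry_c @ rx_c
    den = np.sqrt((rx_c**2).sum() * (ry_c**2).sum(axis=1))
    vals = np.abs(num / den)
    return (1 + np.sum(vals >= obs - 1e-12)) / (1 + n_perm)


# --------------------------------------------------------------------------
# spearman


class TestSpearman:
    def test_perfect_inverse(self):
        rho, _p = spearman([1, 2, 3, 4], [4, 3, 2, 1])
        assert rho == pytest.approx(-1.0)

    def test_identity_gives_p_zero(self):
        rho, p = spearman([1, 5, 2, 9, 4], [1, 5, 2, 9, 4])
        assert rho == pytest.approx(1.0)
        assert p == 0.0

    def test_constant_input_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            spearman([1, 1, 1, 1], [1, 2, 3, 4])

    def test_t_approximation_close_to_permutation_oracle(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=30)
        y = 0.5 * x + rng.normal(size=30)
        _rho, p_t = spearman(x, y)
        n_perm = 100_000
        p_perm = permutation_p_spearman(x, y, n_perm=n_perm)
        se = np.sqrt(p_perm * (1 - p_perm) / n_perm)
        # t-approximation should sit within a few Monte-Carlo SEs plus
        # its own O(1/n) approximation error
        assert abs(p_t - p_perm) < 3 * se + 0.005


class TestCorrelationMatrix:
    def test_two_taxon_simplex_forces_minus_one(self):
        rng = np.random.default_rng(0)
        a = rng.random(20)
        frame = pd.DataFrame([a, 1 - a], index=["A", "B"])
        rho, p = correlation_matrix(frame)
        assert rho.loc["A", "B"] == pytest.approx(-1.0)
        assert p.loc["A", "B"] == 0.0

    def test_sample_permutation_invariance(self):
        rng = np.random.default_rng(1)
        frame = pd.DataFrame(rng.random((4, 15)),
                             index=list("ABCD"))
        rho1, _ = correlation_matrix(frame)
        perm = rng.permutation(15)
        rho2, _ = correlation_matrix(frame.iloc[:, perm])
        pd.testing.assert_frame_equal(rho1, rho2)

    def test_matches_pairwise_op(self):
        rng = np.random.default_rng(2)
        frame = pd.DataFrame(rng.random((5, 12)),
                             index=[f"T{i}" for i in range(5)])
        rho, p = correlation_matrix(frame)
        for i in range(5):
            for j in range(i + 1, 5):
                r2, p2 = spearman(frame.iloc[i], frame.iloc[j])
                assert rho.iloc[i, j] == pytest.approx(r2, abs=1e-12)
                assert p.iloc[i, j] == pytest.approx(p2, abs=1e-12)


# --------------------------------------------------------------------------
# thresholding


class TestBuildNetwork:
    def _mats(self, n, p_fill=0.5):
        idx = [f"T{i}" for i in range(n)]
        rho = pd.DataFrame(np.eye(n) * 0 + 0.3, index=idx, columns=idx)
        p = pd.DataFrame(np.full((n, n), p_fill), index=idx, columns=idx)
        np.fill_diagonal(p.values, 0.0)
        np.fill_diagonal(rho.values, 1.0)
        return rho, p

    def test_single_significant_edge(self):
        rho, p = self._mats(4)
        p.loc["T1", "T2"] = p.loc["T2", "T1"] = 1e-5
        net = build_network(rho, p, alpha=0.001)
        assert net.n_edges == 1
        assert net.graph.has_edge("T1", "T2")

    def test_all_null_gives_isolates(self):
        rho, p = self._mats(5)
        net = build_network(rho, p, alpha=0.001)
        assert net.n_edges == 0
        assert len(net.nodes) == 5

    def test_edge_count_monotone_in_alpha(self):
        rng = np.random.default_rng(0)
        frame = pd.DataFrame(rng.random((10, 40)),
                             index=[f"T{i}" for i in range(10)])
        rho, p = correlation_matrix(frame)
        counts = [
            build_network(rho, p, alpha=a).n_edges
            for a in (0.001, 0.01, 0.05, 0.2)
        ]
        assert counts == sorted(counts)

    def test_alpha_domain(self):
        rho, p = self._mats(3)
        with pytest.raises(GutnetError):
            build_network(rho, p, alpha=1.5)

    def test_planted_pairs_recovered(self):
        frame, planted = planted_correlation_profiles(
            n_samples=310, n_taxa=40, n_pairs=10, rho=0.5, seed=5
        )
        rho, p = correlation_matrix(frame)
        net = build_network(rho, p, alpha=0.001)
        hits = sum(net.graph.has_edge(a, b) for a, b, _s in planted)
        false = net.n_edges - hits
        assert hits >= 9
        assert false <= 5
        # planted signs survive thresholding
        for a, b, sign in planted:
            if net.graph.has_edge(a, b):
                expected = "positive" if sign > 0 else "inverse"
                assert net.graph.edges[a, b]["sign"] == expected

    def test_near_mutual_exclusion_gives_inverse_edge(self):
        # two anchors competing on the simplex: abundance of one crowds out
        # the other, so the surviving edge must be inverse-signed
        rng = np.random.default_rng(3)
        n = 200
        z = rng.random(n)
        a = np.where(z < 0.5, rng.uniform(0.5, 0.8, n), rng.uniform(0.01, 0.1, n))
        b = np.where(z < 0.5, rng.uniform(0.01, 0.1, n), rng.uniform(0.5, 0.8, n))
        rest = 1 - a - b
        frame = pd.DataFrame([a, b, rest], index=["Prevotella", "Bacteroides", "Other"])
        rho, p = correlation_matrix(frame)
        net = build_network(rho, p, alpha=0.001)
        assert net.graph.has_edge("Prevotella", "Bacteroides")
        assert net.graph.edges["Prevotella", "Bacteroides"]["sign"] == "inverse"


# --------------------------------------------------------------------------
# modularity / louvain


def graph_from_edges(edges):
    g = nx.Graph()
    g.add_edges_from(edges)
    return g


class TestModularity:
    def test_singleton_partition_of_triangle(self):
        g = graph_from_edges([(0, 1), (1, 2), (2, 0)])
        q = modularity(g, {0: 0, 1: 1, 2: 2})
        assert q == pytest.approx(-1 / 3)

    def test_all_in_one_is_zero(self):
        rng = np.random.default_rng(0)
        g = nx.gnp_random_graph(8, 0.5, seed=1)
        q = modularity(g, {n: 0 for n in g.nodes})
        assert q == pytest.approx(0.0, abs=1e-12)

    def test_unknown_node_rejected(self):
        g = graph_from_edges([(0, 1)])
        with pytest.raises(GutnetError):
            modularity(g, {0: 0})
        with pytest.raises(GutnetError):
            modularity(g, {0: 0, 1: 0, 9: 0})


class TestLouvain:
    def test_two_triangles(self):
        g = graph_from_edges(
            [(0, 1), (1, 2), (2, 0), (3, 4), (4, 5), (5, 3)]
        )
        part = louvain(g, seed=0)
        assert part.q == pytest.approx(0.5)
        assert len(set(part.modules.values())) == 2
        assert part.modules[0] == part.modules[1] == part.modules[2]

    def test_complete_graph_single_module(self):
        g = nx.complete_graph(5)
        part = louvain(g, seed=0)
        assert len(set(part.modules.values())) == 1
        assert part.q == pytest.approx(0.0, abs=1e-12)

    def test_edgeless_graph_singletons(self):
        g = nx.Graph()
        g.add_nodes_from("abc")
        part = louvain(g, seed=0)
        assert part.q == 0.0
        assert len(set(part.modules.values())) == 3

    def test_planted_partition_recovered(self):
        rng = np.random.default_rng(7)
        blocks = [list(range(10)), list(range(10, 20)), list(range(20, 30))]
        g = nx.Graph()
        g.add_nodes_from(range(30))
        for block in blocks:
            for i, j in itertools.combinations(block, 2):
                if rng.random() < 0.9:
                    g.add_edge(i, j)
        for b1, b2 in itertools.combinations(blocks, 2):
            for i in b1:
                for j in b2:
                    if rng.random() < 0.05:
                        g.add_edge(i, j)
        part = louvain(g, seed=1)
        truth = np.repeat([0, 1, 2], 10)
        found = np.array([part.modules[i] for i in range(30)])
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(truth, found) == 1.0

    def test_deterministic_given_seed(self):
        g = nx.gnp_random_graph(25, 0.15, seed=3)
        p1 = louvain(g, seed=11)
        p2 = louvain(g, seed=11)
        assert p1.modules == p2.modules
        assert p1.q == p2.q

    @pytest.mark.parametrize("seed", range(10))
    def test_near_exhaustive_optimum_small_graphs(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        g = nx.gnp_random_graph(n, 0.45, seed=seed + 100)
        if g.number_of_edges() == 0:
            return
        part = louvain(g, seed=seed)
        best = exhaustive_best_modularity(g)
        assert part.q >= 0.95 * best - 1e-12

    def test_matches_networkx_reference_on_cliques(self):
        # three disjoint cliques: unambiguous optimum, cross-check vs networkx
        g = nx.disjoint_union_all(
            [nx.complete_graph(4), nx.complete_graph(4), nx.complete_graph(5)]
        )
        part = louvain(g, seed=0)
        ref = nx.community.louvain_communities(g, seed=0)
        ref_q = nx.community.modularity(g, ref)
        assert part.q == pytest.approx(ref_q, abs=1e-12)


# --------------------------------------------------------------------------
# sub-networks and taxon-trait networks


class TestDominantSubnetwork:
    def _net(self, edges, nodes=()):
        g = nx.Graph()
        g.add_nodes_from(nodes)
        for a, b in edges:
            g.add_edge(a, b, rho=0.5, p=1e-5, sign="positive", n=None)
        return net_mod.CorrelationNetwork(g, 0.001, "strict-less")

    def test_star_returned_whole(self):
        net = self._net([("Prevotella", x) for x in "abcd"])
        sub = dominant_subnetwork(net, "Prevotella")
        assert set(sub.nodes) == {"Prevotella", "a", "b", "c", "d"}
        assert sub.n_edges == 4

    def test_isolated_anchor(self):
        net = self._net([("a", "b")], nodes=["Prevotella"])
        sub = dominant_subnetwork(net, "Prevotella")
        assert sub.nodes == ["Prevotella"]
        assert sub.n_edges == 0

    def test_only_local_clique_returned(self):
        net = self._net(
            [("P", "a"), ("a", "b"), ("b", "P"), ("x", "y"), ("y", "z"), ("z", "x")]
        )
        sub = dominant_subnetwork(net, "P")
        assert set(sub.nodes) == {"P", "a", "b"}
        assert sub.n_edges == 3

    def test_missing_anchor_rejected(self):
        net = self._net([("a", "b")])
        with pytest.raises(GutnetError):
            dominant_subnetwork(net, "Prevotella")


class TestTraitNetwork:
    def test_copied_taxon_trait_is_perfect_edge(self):
        rng = np.random.default_rng(0)
        taxa = pd.DataFrame(rng.random((3, 30)),
                            index=["A", "B", "C"],
                            columns=[f"S{i}" for i in range(30)])
        traits = pd.DataFrame({"mirror": taxa.loc["A"]},
                              index=taxa.columns)
        net = trait_network(taxa, traits, alpha=0.005)
        assert net.graph.has_edge("A", "mirror")
        assert net.graph.edges["A", "mirror"]["rho"] == pytest.approx(1.0)

    def test_null_false_edge_rate_calibrated(self):
        taxa, traits = null_profiles_and_traits(
            n_samples=310, n_taxa=40, n_traits=25, seed=2
        )
        net = trait_network(taxa, traits, alpha=0.005)
        n_pairs = 40 * 25
        expected = n_pairs * 0.005
        sd = np.sqrt(n_pairs * 0.005 * 0.995)
        assert abs(net.n_edges - expected) <= 3 * sd

    def test_missing_values_pairwise_complete(self):
        rng = np.random.default_rng(1)
        taxa = pd.DataFrame(rng.random((2, 40)),
                            index=["A", "B"],
                            columns=[f"S{i}" for i in range(40)])
        tvals = taxa.loc["A"].copy()
        tvals.iloc[:10] = np.nan
        traits = pd.DataFrame({"partial": tvals})
        net = trait_network(taxa, traits, alpha=0.005)
        assert net.graph.has_edge("A", "partial")
        assert net.graph.edges["A", "partial"]["n"] == 30

    def test_sparse_trait_skipped_with_warning(self):
        rng = np.random.default_rng(2)
        taxa = pd.DataFrame(rng.random((2, 10)),
                            index=["A", "B"],
                            columns=[f"S{i}" for i in range(10)])
        tvals = pd.Series(np.nan, index=taxa.columns)
        tvals.iloc[:3] = [1.0, 2.0, 3.0]
        with pytest.warns(UserWarning, match="fewer than 4"):
            net = trait_network(taxa, pd.DataFrame({"sparse": tvals}), alpha=0.005)
        assert net.n_edges == 0

    def test_planted_effect_power(self):
        # planted |rho|=0.4 at n=310 recovered in >=95% of replicates
        hits = 0
        n_rep = 40
        for seed in range(n_rep):
            rng = np.random.default_rng(1000 + seed)
            r = 2 * np.sin(np.pi * 0.4 / 6)
            z = rng.standard_normal(310)
            taxon = np.exp(z)
            trait = r * z + np.sqrt(1 - r**2) * rng.standard_normal(310)
            taxa = pd.DataFrame([taxon / taxon.sum()], index=["A"],
                                columns=[f"S{i}" for i in range(310)])
            traits = pd.DataFrame({"t": trait}, index=taxa.columns)
            net = trait_network(taxa, traits, alpha=0.005)
            hits += net.graph.has_edge("A", "t")
        assert hits >= 0.95 * n_rep

    def test_opposite_sign_effects_recovered(self):
        rng = np.random.default_rng(4)
        z = rng.standard_normal(310)
        a = np.exp(z)
        b = np.exp(-z + 0.3 * rng.standard_normal(310))
        taxa = pd.DataFrame([a / (a + b), b / (a + b)], index=["A", "B"],
                            columns=[f"S{i}" for i in range(310)])
        traits = pd.DataFrame({"t": z + 0.5 * rng.standard_normal(310)},
                              index=taxa.columns)
        net = trait_network(taxa, traits, alpha=0.005)
        assert net.graph.edges["A", "t"]["sign"] == "positive"
        assert net.graph.edges["B", "t"]["sign"] == "inverse"
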