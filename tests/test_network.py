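import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from conftest import random_table
from ecospart import network as nw
from ecospart.containers import OtuTable
from oracles import (
    betweenness_brute, natural_connectivity_brute,
    shortest_paths_floyd_warshall, zi_pi_brute,
)


def graph_from_edges(edges, nodes=None):
    g = nx.Graph()
    if nodes:
        g.add_nodes_from(nodes)
    g.add_edges_from(edges)
    return g


class TestNetworkFilter:
    def make(self, occurrence_frac, mean_rel, n_samples=20):
        """One target OTU against a constant abundant background."""
        present = int(round(occurrence_frac * n_samples))
        background = 10_000
        per_sample = mean_rel * background / (1 - mean_rel)
        col = [max(1, int(round(per_sample * n_samples / present)))] * present
        col += [0] * (n_samples - present)
        counts = np.column_stack([col, [background] * n_samples])
        return OtuTable(counts, sample_ids=[f"s{i}" for i in range(n_samples)],
                        otu_ids=["target", "bg"])

    def test_low_occurrence_excluded(self):
        t = self.make(0.75, 0.01)
        kept = nw.network_filter(t).otu_ids
        assert "target" not in kept

    def test_low_abundance_excluded_despite_full_occurrence(self):
        t = self.make(1.0, 0.0004)
        kept = nw.network_filter(t).otu_ids
        assert "target" not in kept

    def test_common_abundant_retained(self):
        t = self.make(0.9, 0.001)
        assert "target" in nw.network_filter(t).otu_ids

    def test_empty_result_suggests_thresholds(self):
        t = self.make(0.2, 0.00001)
        with pytest.raises(ValueError, match="relax"):
            nw.network_filter(t, min_occurrence=0.99, min_mean_abund=2.0)


class TestBuildNetwork:
    def test_perfect_rank_correlation_gives_edge(self):
        x = np.arange(1, 11)
        counts = np.column_stack([x, x * 3, 11 - x])
        t = OtuTable(counts, sample_ids=[f"s{i}" for i in range(10)],
                     otu_ids=["a", "b", "c"])
        g = nw.build_network(t)
        assert g.has_edge("a", "b")
        assert g["a"]["b"]["rho"] == pytest.approx(1.0)
        assert g.has_edge("a", "c") and g["a"]["c"]["sign"] == -1

    def test_same_inputs_identical_edge_list(self, rng):
        t = random_table(rng, 12, 15)
        g1 = nw.build_network(t)
        g2 = nw.build_network(t)
        assert sorted(g1.edges) == sorted(g2.edges)

    def test_constant_otu_isolated(self):
        x = np.arange(1, 11)
        counts = np.column_stack([x, x * 2, np.full(10, 7)])
        t = OtuTable(counts, sample_ids=[f"s{i}" for i in range(10)],
                     otu_ids=["a", "b", "const"])
        g = nw.build_network(t)
        assert g.degree("const") == 0

    def test_false_discovery_rate_controlled(self, rng):
        # i.i.d. noise: BH keeps the expected fraction of significant
        # edges at or below q over repeated draws
        hits = trials = 0
        for rep in range(20):
            counts = rng.integers(0, 1000, size=(30, 50)) + 1
            t = OtuTable(counts, sample_ids=[f"s{i}" for i in range(30)],
                         otu_ids=[f"o{j}" for j in range(50)])
            g = nw.build_network(t, r_threshold=0.0, q_threshold=0.05)
            hits += g.number_of_edges()
            trials += 50 * 49 // 2
        assert hits / trials <= 0.05


class TestTopology:
    def test_triangle_closed_forms(self):
        g = graph_from_edges([(1, 2), (2, 3), (1, 3)])
        glob, per_node = nw.topology_metrics(g)
        assert glob["density"] == pytest.approx(1.0)
        assert glob["avgK"] == pytest.approx(2.0)
        assert glob["diameter"] == 1
        assert glob["avg_path_length"] == pytest.approx(1.0)
        assert (per_node["betweenness"] == 0).all()

    def test_path_graph_betweenness(self):
        g = graph_from_edges([("a", "b"), ("b", "c")])
        glob, per_node = nw.topology_metrics(g)
        assert glob["diameter"] == 2
        assert per_node.loc["b", "betweenness"] == pytest.approx(1.0)

    def test_random_graphs_match_brute_force(self, rng):
        for rep in range(8):
            g = nx.gnp_random_graph(8, 0.4, seed=int(rng.integers(1e6)))
            if g.number_of_edges() == 0:
                continue
            adj = nx.to_numpy_array(g).astype(int).tolist()
            _, per_node = nw.topology_metrics(g)
            bc = betweenness_brute(adj)
            for v in g.nodes:
                assert per_node.loc[v, "degree"] == sum(adj[v])
                assert per_node.loc[v, "betweenness"] == pytest.approx(
                    bc[v], abs=1e-12)
            comp = max(nx.connected_components(g), key=len)
            sub = sorted(comp)
            d = shortest_paths_floyd_warshall(
                [[adj[i][j] for j in sub] for i in sub])
            finite = [d[i][j] for i in range(len(sub))
                      for j in range(len(sub)) if i != j]
            glob, _ = nw.topology_metrics(g)
            assert glob["diameter"] == max(finite)
            assert glob["avg_path_length"] == pytest.approx(
                sum(finite) / len(finite), abs=1e-12)


class TestModulesAndRoles:
    def test_two_cliques_two_modules(self):
        g = nx.union(nx.complete_graph(range(4)),
                     nx.complete_graph(range(10, 14)))
        mods = nw.detect_modules(g, seed=0)
        assert mods.nunique() == 2
        assert len(set(mods[list(range(4))])) == 1

    def test_same_seed_same_partition(self, rng):
        g = nx.gnp_random_graph(30, 0.2, seed=7)
        pd.testing.assert_series_equal(nw.detect_modules(g, seed=3),
                                       nw.detect_modules(g, seed=3))

    def test_planted_partition_recovered(self):
        from sklearn.metrics import adjusted_rand_score
        scores = []
        for seed in range(10):
            g = nx.planted_partition_graph(4, 12, 0.9, 0.05, seed=seed)
            truth = [v // 12 for v in range(48)]
            mods = nw.detect_modules(nx.Graph(g), seed=seed)
            scores.append(adjusted_rand_score(
                truth, [mods[v] for v in range(48)]))
        assert np.mean(scores) >= 0.9

    def test_all_edges_inside_module_pi_zero(self):
        g = nx.complete_graph(range(5))
        mods = pd.Series(0, index=list(g.nodes))
        roles = nw.zi_pi(g, mods)
        assert (roles["Pi"] == 0).all()

    def test_even_split_pi_half(self):
        g = graph_from_edges([("x", "a"), ("x", "b")])
        mods = pd.Series({"x": 0, "a": 0, "b": 1})
        roles = nw.zi_pi(g, mods)
        assert roles.loc["x", "Pi"] == pytest.approx(0.5)

    def test_bridge_node_matches_brute_force_and_connector_rule(self):
        # three 6-cliques; a bridge node linked to 2 nodes in each clique
        g = nx.Graph()
        for c in range(3):
            g.update(nx.complete_graph(range(10 * c, 10 * c + 6)))
        for c in range(3):
            g.add_edge("bridge", 10 * c)
            g.add_edge("bridge", 10 * c + 1)
        mods = nw.detect_modules(g, seed=0)
        roles = nw.zi_pi(g, mods)
        nodes = list(g.nodes)
        adj = nx.to_numpy_array(g, nodelist=nodes).astype(int).tolist()
        brute = zi_pi_brute(adj, [mods[v] for v in nodes])
        for v, (zi, pi) in zip(nodes, brute):
            assert roles.loc[v, "Zi"] == pytest.approx(zi, abs=1e-12)
            assert roles.loc[v, "Pi"] == pytest.approx(pi, abs=1e-12)
        # evenly split over 3 modules: Pi = 1 - 3*(1/3)^2 = 2/3 > 0.62
        assert roles.loc["bridge", "Pi"] == pytest.approx(2 / 3)
        assert roles.loc["bridge", "category"] == "connector"
        assert roles.loc["bridge", "keystone"]


class TestCohesion:
    def test_weighted_sum_arithmetic(self):
        # hand-checkable: abundances [0.5, 0.5] and connectedness [0.2, 0.4]
        conn = np.array([0.2, 0.4])
        a = np.array([0.5, 0.5])
        assert a @ conn == pytest.approx(0.3)

    def test_sign_constraints_on_random_tables(self, rng):
        for _ in range(10):
            t = random_table(rng, 8, 10)
            per_sample, per_taxon = nw.cohesion(t)
            assert (per_sample["C_pos"] >= -1e-12).all()
            assert (per_sample["C_neg"] <= 1e-12).all()
            assert (per_taxon["connectedness_pos"] >= 0).all()
            assert (per_taxon["connectedness_neg"] <= 0).all()

    def test_single_taxon_zero_cohesion(self):
        t = OtuTable([[3], [4], [5]], sample_ids=["a", "b", "c"],
                     otu_ids=["only"])
        per_sample, _ = nw.cohesion(t)
        assert (per_sample == 0).all().all()

    def test_null_corrected_mode_shrinks_toward_zero(self, rng):
        t = random_table(rng, 10, 8)
        plain, _ = nw.cohesion(t, mode="paper")
        corrected, _ = nw.cohesion(t, mode="null_corrected", n_null=50,
                                   seed=1)
        assert np.isfinite(corrected.to_numpy()).all()


class TestNaturalConnectivity:
    def test_edgeless_graph_zero(self):
        g = nx.empty_graph(7)
        assert nw.natural_connectivity(g) == pytest.approx(0.0, abs=1e-12)

    def test_single_edge_ln_cosh(self):
        g = graph_from_edges([(0, 1)])
        assert nw.natural_connectivity(g) == pytest.approx(
            np.log(np.cosh(1.0)), abs=1e-12)

    def test_triangle_closed_form(self):
        g = graph_from_edges([(0, 1), (1, 2), (0, 2)])
        expect = np.log((np.exp(2) + 2 * np.exp(-1)) / 3)
        assert nw.natural_connectivity(g) == pytest.approx(expect, abs=1e-12)

    def test_matches_matrix_exponential_oracle(self, rng):
        for _ in range(10):
            g = nx.gnp_random_graph(7, 0.5, seed=int(rng.integers(1e6)))
            adj = nx.to_numpy_array(g)
            assert nw.natural_connectivity(g) == pytest.approx(
                natural_connectivity_brute(adj), abs=1e-10)

    def test_monotone_under_edge_removal(self):
        # exhaustively on all connected graphs with up to 5 nodes (sampled
        # by edge subsets of K5), removing any edge never increases NC
        base = list(itertools.combinations(range(5), 2))
        rng = np.random.default_rng(0)
        checked = 0
        for _ in range(40):
            mask = rng.random(len(base)) < 0.6
            edges = [e for e, m in zip(base, mask) if m]
            g = graph_from_edges(edges, nodes=range(5))
            if not nx.is_connected(g):
                continue
            nc = nw.natural_connectivity(g)
            for e in list(g.edges):
                h = g.copy()
                h.remove_edge(*e)
                assert nw.natural_connectivity(h) <= nc + 1e-12
                checked += 1
        assert checked > 20


class TestRobustness:
    def hub_graph(self, seed=0):
        g = nx.barbell_graph(6, 0)
        rng = np.random.default_rng(seed)
        for v in range(12, 24):
            g.add_edge(v, int(rng.integers(0, 12)))
        return g

    def test_star_hub_removal_hurts_most(self):
        g = nx.star_graph(8)
        nc0 = nw.natural_connectivity(g)
        no_hub = g.copy(); no_hub.remove_node(0)
        no_leaf = g.copy(); no_leaf.remove_node(3)
        assert nw.natural_connectivity(no_hub) < nw.natural_connectivity(
            no_leaf) < nc0

    def test_curve_stops_at_last_non_empty_graph(self):
        g = nx.path_graph(4)
        rb = nw.robustness(g, "random", step=0.25, reps=3, seed=1)
        assert rb.points["fraction_removed"].iloc[0] == 0.0
        assert rb.points["fraction_removed"].is_monotonic_increasing
        assert rb.points["fraction_removed"].iloc[-1] < 1.0
        assert rb.nc_before == pytest.approx(
            nw.natural_connectivity(g))

    def test_keystone_first_steeper_than_random_on_hub_graph(self):
        wins = 0
        for seed in range(10):
            g = self.hub_graph(seed)
            roles = nw.zi_pi(g, nw.detect_modules(g, seed=seed))
            if not roles["keystone"].any():
                deg = pd.Series(dict(g.degree()))
                roles.loc[deg.nlargest(3).index, "category"] = "module_hub"
                roles.loc[deg.nlargest(3).index, "keystone"] = True
            frac = max(0.1, roles["keystone"].sum() / g.number_of_nodes())
            rk = nw.robustness(g, "keystone_first", step=0.05, reps=10,
                               seed=seed, roles=roles, max_fraction=frac)
            rr = nw.robustness(g, "random", step=0.05, reps=10, seed=seed,
                               max_fraction=frac)
            wins += rk.slope < rr.slope
        assert wins >= 9

    def test_class_removal_reports_before_and_after(self):
        g = graph_from_edges([("a", "b"), ("b", "c"), ("c", "d")])
        for v, cls in zip("abcd", ["specialist", "specialist",
                                   "generalist", "generalist"]):
            g.nodes[v]["habitat_class"] = cls
        rb = nw.robustness(g, "remove_specialists", step=0.5, reps=4, seed=0)
        assert rb.nc_before == pytest.approx(nw.natural_connectivity(g))
        h = g.copy(); h.remove_nodes_from(["a", "b"])
        assert rb.nc_after == pytest.approx(nw.natural_connectivity(h))

    def test_unknown_class_rejected(self):
        g = graph_from_edges([("a", "b")])
        with pytest.raises(ValueError):
            nw.robustness(g, "remove_specialists", seed=0)
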