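import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from succnet.synth import planted_hub_network
from succnet.topology import (
    classify_role,
    global_metrics,
    keystone_taxonomy_profile,
    louvain_partition,
    modularity_zscore,
    module_size_stats,
    two_clique_bridge,
    zipi_roles,
)


def newman_q(graph, communities):
    """Independent direct evaluation of Q = sum_c (e_c/m - (d_c/2m)^2)."""
    m = graph.number_of_edges()
    q = 0.0
    for c in communities:
        e_c = sum(1 for u, v in graph.edges if u in c and v in c)
        d_c = sum(graph.degree(v) for v in c)
        q += e_c / m - (d_c / (2 * m)) ** 2
    return q


class TestGlobalMetrics:
    def test_complete_graph(self):
        g = nx.complete_graph(4)
        part = louvain_partition(g, seed=0)
        met = global_metrics(g, part)
        assert met.avg_degree == pytest.approx(3.0)
        assert met.avg_clustering == pytest.approx(1.0)

    def test_path_graph_avg_path_length(self):
        g = nx.path_graph(3)
        met = global_metrics(g, louvain_partition(g, seed=0))
        assert met.avg_path_length == pytest.approx(4.0 / 3.0)

    def test_disjoint_triangles_connected_pairs_only(self):
        g = nx.Graph()
        g.add_edges_from([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])
        met = global_metrics(g, louvain_partition(g, seed=0))
        assert met.n_connected_pairs == 6
        assert met.avg_path_length == pytest.approx(1.0)

    def test_empty_graph_nan(self):
        g = nx.Graph()
        with pytest.warns(UserWarning):
            met = global_metrics(g, louvain_partition(g, seed=0))
        assert np.isnan(met.avg_degree)


class TestLouvain:
    def test_two_clique_bridge_oracle(self):
        g = two_clique_bridge(4)
        part = louvain_partition(g, seed=0)
        assert part.n_modules == 2
        expected = 12.0 / 13.0 - 0.5  # direct Newman evaluation, m=13
        assert part.modularity == pytest.approx(expected, abs=1e-9)
        assert newman_q(g, part.communities()) == pytest.approx(part.modularity)

    def test_single_clique_single_module(self):
        part = louvain_partition(nx.complete_graph(6), seed=0)
        assert part.n_modules == 1

    def test_edgeless_graph(self):
        g = nx.Graph()
        g.add_nodes_from(range(5))
        part = louvain_partition(g, seed=0)
        assert part.n_modules == 5
        assert part.modularity == 0.0

    def test_deterministic(self):
        g, _, _ = planted_hub_network(seed=2)
        p1 = louvain_partition(g, seed=7)
        p2 = louvain_partition(g, seed=7)
        assert p1.membership == p2.membership

    def test_planted_module_recovery(self):
        aris = []
        for seed in range(5):
            g, membership, roles = planted_hub_network(seed=seed)
            part = louvain_partition(g, seed=0)
            members = list(membership)
            true = [membership[v] for v in members]
            found = [part.membership[v] for v in members]
            aris.append(adjusted_rand_score(true, found))
        assert np.mean(aris) >= 0.8


class TestModuleSizeStats:
    @pytest.mark.parametrize("nodes,modules,expected", [
        (426, 119, 3.58),
        (785, 145, 5.41),
        (359, 165, 2.18),
        (657, 161, 4.08),
    ])
    def test_stage_table_values(self, nodes, modules, expected):
        assert module_size_stats(nodes, modules) == (modules, expected)

    def test_all_singletons(self):
        assert module_size_stats(7, 7) == (7, 1.0)

    def test_accepts_partition(self):
        part = louvain_partition(two_clique_bridge(4), seed=0)
        n_mod, avg = module_size_stats(part)
        assert (n_mod, avg) == (2, 4.0)


class TestZiPi:
    def test_all_intramodular_pi_zero(self):
        g = two_clique_bridge(4)
        part = louvain_partition(g, seed=0)
        roles = zipi_roles(g, part)
        inner = roles.loc["a1"]  # clique member without the bridge
        assert inner["pi"] == pytest.approx(0.0)

    def test_pi_even_split_hand_value(self):
        # degree-4 node split 2/2 across two modules -> Pi = 0.5
        g = nx.Graph()
        g.add_edges_from([("x", "a1"), ("x", "a2"), ("x", "b1"), ("x", "b2"),
                          ("a1", "a2"), ("b1", "b2")])
        part_membership = {"x": 0, "a1": 0, "a2": 0, "b1": 1, "b2": 1}
        from succnet.topology import ModulePartition
        part = ModulePartition(part_membership, 0.0, 2, 2.5)
        roles = zipi_roles(g, part)
        assert roles.loc["x", "pi"] == pytest.approx(0.5)

    def test_threshold_boxes(self):
        assert classify_role(3.0, 0.7) == "NetworkHub"
        assert classify_role(3.0, 0.62) == "ModuleHub"
        assert classify_role(2.5, 0.7) == "Connector"
        assert classify_role(2.5, 0.62) == "Peripheral"

    def test_role_boxes_tile_the_plane(self):
        # every (Zi, Pi) grid point gets exactly one role
        for zi in np.linspace(-3, 6, 19):
            for pi in np.linspace(0, 1, 21):
                roles = [r for r in ("Peripheral", "Connector", "ModuleHub", "NetworkHub")
                         if r == classify_role(zi, pi)]
                assert len(roles) == 1

    def test_pi_bounds_and_isolated_nodes(self):
        g, membership, _ = planted_hub_network(seed=1)
        g.add_node("isolated")
        part = louvain_partition(g, seed=0)
        roles = zipi_roles(g, part)
        assert roles.loc["isolated", "pi"] == 0.0
        assert roles.loc["isolated", "role"] == "Peripheral"
        assert ((roles["pi"] >= 0) & (roles["pi"] <= 1)).all()
        # Pi = 0 iff all edges intramodular
        intra = roles["pi"] == 0
        for v in roles.index[intra]:
            mods = {part.membership[u] for u in g.neighbors(v)}
            assert mods <= {part.membership[v]}

    def test_uniform_module_zi_zero(self):
        g = nx.complete_graph(5)
        part = louvain_partition(g, seed=0)
        roles = zipi_roles(g, part)
        assert (roles["zi"] == 0.0).all()


class TestNullModel:
    def test_bridge_graph_beats_random(self):
        g = two_clique_bridge(4)
        res = modularity_zscore(g, n_random=60, seed=0, restarts=3)
        assert res.z > 0
        assert res.n_random == 60
        assert len(res.ensemble) == 60

    def test_z_formula(self):
        g = two_clique_bridge(4)
        res = modularity_zscore(g, n_random=40, seed=1, restarts=3)
        expected = (res.q_obs - res.q_rand_mean) / res.q_rand_sd
        assert res.z == pytest.approx(expected)

    def test_node_relabeling_invariance(self):
        g = two_clique_bridge(4)
        h = nx.relabel_nodes(g, {v: f"x_{v}" for v in g.nodes})
        r1 = modularity_zscore(g, n_random=40, seed=3, restarts=3)
        r2 = modularity_zscore(h, n_random=40, seed=3, restarts=3)
        assert r1.q_rand_mean == r2.q_rand_mean  # same null ensemble
        assert r1.z == pytest.approx(r2.z, abs=0.2)

    def test_self_null_small_z(self):
        g = nx.gnm_random_graph(40, 80, seed=5)
        res = modularity_zscore(g, n_random=60, seed=0, restarts=3)
        assert abs(res.z) <= 3.5

    def test_degenerate_input_rejected(self):
        g = nx.Graph()
        g.add_node("a")
        with pytest.raises(ValueError):
            modularity_zscore(g)


class TestKeystoneProfile:
    def test_counting(self):
        roles = pd.DataFrame({
            "role": ["Connector"] * 3 + ["Peripheral"],
            "phylum": ["A", "A", "B", "C"],
        }, index=["o1", "o2", "o3", "o4"])
        prof = keystone_taxonomy_profile(roles)
        assert prof.loc["Connector", "A"] == pytest.approx(2 / 3)
        assert prof.loc["Connector", "B"] == pytest.approx(1 / 3)
        np.testing.assert_allclose(prof.sum(axis=1), 1.0)

    def test_no_keystones_empty_profile(self):
        roles = pd.DataFrame({"role": ["Peripheral"] * 4,
                              "phylum": ["A", "B", "A", "B"]})
        assert keystone_taxonomy_profile(roles).empty
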