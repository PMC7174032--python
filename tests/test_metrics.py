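"""Graph measures against brute-force oracles and structural properties."""

import networkx as nx
import numpy as np
import pytest

from cognet import (
    Connectome,
    SubnetworkDefinition,
    clustering_coefficient,
    degree_centrality,
    global_efficiency,
    identify_hubs,
    local_efficiency,
    shortest_path_lengths,
)
from cognet.metrics import metric_table, strength, subject_metrics

from oracles import (
    brute_force_clustering,
    brute_force_degree,
    brute_force_global_efficiency,
    brute_force_local_efficiency,
    brute_force_shortest_paths,
    random_weighted_graph,
)


def star(n: int) -> np.ndarray:
    w = np.zeros((n, n))
    w[0, 1:] = w[1:, 0] = 1.0
    return w


def path3() -> np.ndarray:
    w = np.zeros((3, 3))
    w[0, 1] = w[1, 0] = w[1, 2] = w[2, 1] = 1.0
    return w


def triangle(w01=1.0, w02=1.0, w12=1.0) -> np.ndarray:
    w = np.zeros((3, 3))
    w[0, 1] = w[1, 0] = w01
    w[0, 2] = w[2, 0] = w02
    w[1, 2] = w[2, 1] = w12
    return w


class TestDegree:
    def test_star(self):
        k = degree_centrality(star(6))
        assert k[0] == 5 and np.all(k[1:] == 1)

    def test_empty(self):
        assert np.all(degree_centrality(np.zeros((4, 4))) == 0)

    def test_matches_brute_force(self, rng):
        for _ in range(20):
            w = random_weighted_graph(rng, 8)
            np.testing.assert_array_equal(degree_centrality(w), brute_force_degree(w))


class TestShortestPaths:
    def test_unit_path(self):
        d = shortest_path_lengths(path3())
        assert d[0, 2] == pytest.approx(2.0)

    def test_disconnected_is_inf(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 1.0
        d = shortest_path_lengths(w)
        assert np.isinf(d[0, 2])
        assert d[0, 0] == 0.0

    def test_matches_simple_path_enumeration(self, rng):
        for _ in range(10):
            w = random_weighted_graph(rng, 7, density=0.4)
            np.testing.assert_allclose(
                shortest_path_lengths(w), brute_force_shortest_paths(w), atol=1e-10
            )


class TestGlobalEfficiency:
    def test_complete_unit_graph_is_one(self):
        w = 1.0 - np.eye(5)
        assert global_efficiency(w) == pytest.approx(1.0)

    def test_empty_graph_is_zero(self):
        assert global_efficiency(np.zeros((4, 4))) == 0.0

    def test_three_node_unit_path(self):
        # ordered pairs: four at distance 1, two at distance 2 -> 5/6
        assert global_efficiency(path3()) == pytest.approx(5.0 / 6.0)

    def test_single_node_error(self):
        with pytest.raises(ValueError):
            global_efficiency(np.zeros((1, 1)))

    def test_removing_edge_never_increases(self, rng):
        for _ in range(10):
            w = random_weighted_graph(rng, 7)
            e = global_efficiency(w)
            edges = np.argwhere(np.triu(w) > 0)
            if not len(edges):
                continue
            i, j = edges[rng.integers(len(edges))]
            w2 = w.copy()
            w2[i, j] = w2[j, i] = 0.0
            assert global_efficiency(w2) <= e + 1e-12


class TestLocalEfficiency:
    def test_unit_triangle_all_one(self):
        np.testing.assert_allclose(local_efficiency(triangle()), 1.0)

    def test_star_all_zero(self):
        np.testing.assert_allclose(local_efficiency(star(5)), 0.0)

    def test_matches_neighbour_subgraph_oracle(self, rng):
        for _ in range(10):
            w = random_weighted_graph(rng, 8)
            np.testing.assert_allclose(
                local_efficiency(w), brute_force_local_efficiency(w), atol=1e-10
            )


class TestClustering:
    def test_uniform_triangle_is_one(self):
        np.testing.assert_allclose(clustering_coefficient(triangle(2, 2, 2)), 1.0)

    def test_path_graph_zero(self):
        np.testing.assert_allclose(clustering_coefficient(path3()), 0.0)

    def test_hand_computed_weighted_triangle(self):
        # normalized weights {1, 1, 0.125}: (1*1*0.125)^(1/3) = 0.5 per pair
        np.testing.assert_allclose(
            clustering_coefficient(triangle(1.0, 1.0, 0.125)), 0.5
        )

    def test_matches_brute_force_and_networkx(self, rng):
        for _ in range(10):
            w = random_weighted_graph(rng, 8)
            ours = clustering_coefficient(w)
            np.testing.assert_allclose(ours, brute_force_clustering(w), atol=1e-10)
            g = nx.from_numpy_array(w)
            theirs = nx.clustering(g, weight="weight")
            np.testing.assert_allclose(
                ours, [theirs[i] for i in range(8)], atol=1e-10
            )


class TestProperties:
    def test_permutation_equivariance(self, rng):
        w = random_weighted_graph(rng, 8)
        perm = rng.permutation(8)
        wp = w[np.ix_(perm, perm)]
        np.testing.assert_allclose(degree_centrality(wp), degree_centrality(w)[perm])
        np.testing.assert_allclose(
            clustering_coefficient(wp), clustering_coefficient(w)[perm], atol=1e-12
        )
        np.testing.assert_allclose(
            local_efficiency(wp), local_efficiency(w)[perm], atol=1e-12
        )
        assert global_efficiency(wp) == pytest.approx(global_efficiency(w))

    def test_uniform_rescaling(self, rng):
        w = random_weighted_graph(rng, 7)
        c = 3.7
        np.testing.assert_array_equal(degree_centrality(c * w), degree_centrality(w))
        np.testing.assert_allclose(
            clustering_coefficient(c * w), clustering_coefficient(w), atol=1e-12
        )
        assert global_efficiency(c * w) == pytest.approx(c * global_efficiency(w))
        np.testing.assert_allclose(
            local_efficiency(c * w), c * local_efficiency(w), atol=1e-10
        )

    def test_binary_graph_reduces_to_binary_definitions(self, rng):
        for _ in range(5):
            w = (random_weighted_graph(rng, 8) > 0).astype(float)
            g = nx.from_numpy_array(w)
            np.testing.assert_allclose(
                clustering_coefficient(w),
                [nx.clustering(g)[i] for i in range(8)],
                atol=1e-10,
            )
            if g.number_of_nodes() > 1:
                assert global_efficiency(w) == pytest.approx(
                    nx.global_efficiency(g), abs=1e-10
                )

    def test_strength_is_weight_sum(self, rng):
        w = random_weighted_graph(rng, 6)
        np.testing.assert_allclose(strength(w), w.sum(1))


class TestHubs:
    def test_printed_hub_counts(self, rng, atlas):
        controls = [random_weighted_graph(rng, 90) for _ in range(4)]
        labels = atlas.node_labels
        wm = identify_hubs(
            controls, SubnetworkDefinition("wm", atlas.wm_members), node_labels=labels
        )
        rsn = identify_hubs(
            controls, SubnetworkDefinition("rsn", atlas.rsn_members), node_labels=labels
        )
        assert len(wm) == 6
        assert len(rsn) == 5

    def test_ten_node_network_two_hubs(self, rng):
        labels = [f"n{i}" for i in range(20)]
        controls = [random_weighted_graph(rng, 20) for _ in range(3)]
        hubs = identify_hubs(
            controls, SubnetworkDefinition("s", labels[:10]), node_labels=labels
        )
        assert len(hubs) == 2

    def test_hubs_are_highest_degree_members(self):
        w = np.zeros((6, 6))
        # node 0 degree 3, node 1 degree 2, others fewer
        for i, j in [(0, 1), (0, 2), (0, 3), (1, 2)]:
            w[i, j] = w[j, i] = 1.0
        labels = [f"n{i}" for i in range(6)]
        hubs = identify_hubs(
            [w], SubnetworkDefinition("s", labels), node_labels=labels
        )
        assert hubs == ["n0"]

    def test_tie_break_by_member_order(self):
        w = np.zeros((5, 5))
        w[3, 4] = w[4, 3] = 1.0  # all of n0..n2 tied at degree 0
        labels = [f"n{i}" for i in range(5)]
        hubs = identify_hubs(
            [w], SubnetworkDefinition("s", ["n2", "n0", "n1", "n3", "n4"]),
            node_labels=labels,
        )
        assert hubs == ["n3"]  # degree 1 beats ties; floor(0.2*5)=1

    def test_empty_controls_error(self, atlas):
        with pytest.raises(ValueError):
            identify_hubs([], SubnetworkDefinition("wm", atlas.wm_members))


class TestMetricTable:
    def test_long_format_contents(self, rng):
        w = {f"s{i}": random_weighted_graph(rng, 6) for i in range(3)}
        nets = {"a": np.array([0, 1, 2]), "b": np.array([3, 4, 5])}
        labels = {"a": ["n0", "n1", "n2"], "b": ["n3", "n4", "n5"]}
        tbl = metric_table(w, nets, labels, threshold=2.5,
                          groups={f"s{i}": "control" for i in range(3)})
        # 3 subjects x 2 networks x (3 global + 3 metrics x 3 nodes)
        assert len(tbl) == 3 * 2 * (3 + 9)
        sub = tbl.query("subject_id=='s0' and network=='a' and metric=='degree'")
        m = subject_metrics(w["s0"][np.ix_(nets["a"], nets["a"])])
        np.testing.assert_allclose(sub["value"].to_numpy(), m["degree"])
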