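import numpy as np
import pytest

from fosnet.errors import DomainError, FosnetError
from fosnet.metrics import (
    betweenness,
    clustering_coefficient,
    compare_group_metrics,
    degree,
    global_efficiency,
    metric_table,
    nodal_efficiency,
    weighted_distances,
)
from fosnet.networks import FunctionalNetwork
from fosnet.smallworld import watts_strogatz

from .conftest import make_network, random_weighted_network
from .oracles import (
    betweenness_by_enumeration,
    efficiency_from_distances,
    relaxation_distances,
)


class TestDegree:
    def test_isolated_node(self, fragmented12):
        assert degree(fragmented12, "DG") == 0

    def test_complete_network(self, complete12):
        assert all(degree(complete12, n) == 11 for n in complete12.nodes)

    def test_path_middle(self, path3):
        assert degree(path3, "B") == 2
        assert degree(path3, "A") == 1

    def test_unknown_node(self, path3):
        with pytest.raises(KeyError):
            degree(path3, "Z")


class TestBetweenness:
    def test_star_center_closed_form(self, star12):
        # (n-1)(n-2)/2 = 55 at n=12
        assert betweenness(star12, "hub") == pytest.approx(55.0)

    def test_star_leaf(self, star12):
        assert betweenness(star12, "leaf0") == pytest.approx(0.0)

    def test_path_middle(self, path3):
        assert betweenness(path3, "B") == pytest.approx(1.0)

    def test_fractional_credit_on_tied_geodesics(self):
        # square A-B-C-D-A: two geodesics A..C, each through one of B/D
        net = make_network(
            [("A", "B", 1), ("B", "C", 1), ("C", "D", 1), ("D", "A", 1)]
        )
        assert betweenness(net, "B") == pytest.approx(0.5)

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(123)
        for _ in range(30):
            net = random_weighted_network(rng)
            adj = net.adjacency().tolist()
            expected = betweenness_by_enumeration(adj)
            assert np.allclose(betweenness(net), expected, atol=1e-12)

    def test_tree_total_matches_oracle(self):
        net = make_network(
            [("r", "a", 1), ("r", "b", 1), ("a", "c", 1), ("a", "d", 1), ("b", "e", 1)]
        )
        expected = betweenness_by_enumeration(net.adjacency().tolist())
        assert betweenness(net).sum() == pytest.approx(expected.sum())


class TestWeightedDistances:
    def test_single_edge(self):
        net = make_network([("A", "B", 0.8)])
        d = weighted_distances(net)
        assert d[0, 1] == pytest.approx(1.25)

    def test_two_hop(self):
        net = make_network([("A", "B", 0.5), ("B", "C", 0.5)])
        d = weighted_distances(net)
        assert d[0, 2] == pytest.approx(4.0)

    def test_disconnected_infinite(self, fragmented12):
        d = weighted_distances(fragmented12)
        i = fragmented12.nodes.index("DG")
        j = fragmented12.nodes.index("BLA")
        assert np.isinf(d[i, j])
        assert d[i, i] == 0.0

    def test_zero_weight_edge_rejected(self):
        net = FunctionalNetwork("g", ("A", "B"), (("A", "B", 0.0),), threshold=-1.0)
        with pytest.raises(DomainError):
            weighted_distances(net)

    def test_matches_relaxation_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            net = random_weighted_network(rng)
            d = weighted_distances(net)
            oracle = relaxation_distances(net.nodes, net.edges)
            for i, a in enumerate(net.nodes):
                for j, b in enumerate(net.nodes):
                    assert (
                        d[i, j] == oracle[a][b]
                        or abs(d[i, j] - oracle[a][b]) < 1e-12
                    )


class TestEfficiency:
    def test_single_edge_nodal(self):
        net = make_network([("A", "B", 0.8)])
        assert nodal_efficiency(net, "A") == pytest.approx(0.8)
        assert nodal_efficiency(net, "B") == pytest.approx(0.8)

    def test_complete_unit_network(self, complete12):
        assert nodal_efficiency(complete12, "n0") == pytest.approx(1.0)
        assert global_efficiency(complete12) == pytest.approx(1.0)

    def test_isolated_node_zero(self, fragmented12):
        assert nodal_efficiency(fragmented12, "DG") == 0.0

    def test_path_hand_computed(self, path3):
        # distances 2 and 4 -> nodal (0.375, 0.5, 0.375); mean 0.41667
        eff = nodal_efficiency(path3)
        assert eff == pytest.approx([0.375, 0.5, 0.375])
        assert global_efficiency(path3) == pytest.approx(0.41667, abs=1e-5)

    def test_empty_network_zero(self, empty12):
        assert global_efficiency(empty12) == 0.0

    def test_global_is_mean_of_nodal(self):
        rng = np.random.default_rng(11)
        net = random_weighted_network(rng, n=8)
        assert global_efficiency(net) == pytest.approx(np.mean(nodal_efficiency(net)))

    def test_nodal_bounded_by_max_incident_weight(self):
        rng = np.random.default_rng(13)
        for _ in range(25):
            net = random_weighted_network(rng)
            w = net.weight_matrix()
            eff = nodal_efficiency(net)
            assert np.all(eff <= w.max(axis=1) + 1e-12)

    def test_adding_edge_never_decreases_global_efficiency(self):
        rng = np.random.default_rng(17)
        for _ in range(25):
            net = random_weighted_network(rng, p_edge=0.4)
            absent = [
                (a, b)
                for i, a in enumerate(net.nodes)
                for b in net.nodes[i + 1 :]
                if not any({a, b} == {x, y} for x, y, _ in net.edges)
            ]
            if not absent:
                continue
            a, b = absent[rng.integers(len(absent))]
            bigger = make_network(
                [*net.edges, (a, b, float(rng.uniform(0.1, 1.0)))], nodes=net.nodes
            )
            assert global_efficiency(bigger) >= global_efficiency(net) - 1e-12

    def test_matches_relaxation_oracle(self):
        rng = np.random.default_rng(19)
        for _ in range(20):
            net = random_weighted_network(rng)
            oracle_d = relaxation_distances(net.nodes, net.edges)
            nodal_o, global_o = efficiency_from_distances(oracle_d, net.nodes)
            assert np.allclose(
                nodal_efficiency(net), [nodal_o[n] for n in net.nodes], atol=1e-12
            )
            assert global_efficiency(net) == pytest.approx(global_o, abs=1e-12)


class TestClustering:
    def test_triangle(self):
        net = make_network([("A", "B", 1), ("B", "C", 1), ("A", "C", 1)])
        assert clustering_coefficient(net) == pytest.approx(1.0)

    def test_path(self, path3):
        assert clustering_coefficient(path3) == pytest.approx(0.0)

    def test_ring_lattice_closed_form(self):
        # n=12, k=4 lattice: 3(k-2)/(4(k-1)) = 0.5
        net = watts_strogatz(12, 4, 0.0, seed=0)
        assert clustering_coefficient(net) == pytest.approx(0.5)

    def test_weighted_variant_bounded(self):
        rng = np.random.default_rng(23)
        net = random_weighted_network(rng, n=8)
        cw = clustering_coefficient(net, weighted=True)
        assert 0.0 <= cw <= 1.0


class TestMetricTable:
    def test_star_center_ranks_first(self, star12):
        t = metric_table(star12)
        row = t.frame.loc["hub"]
        assert row["rank_degree"] == 1.0
        assert row["rank_betweenness"] == 1.0
        assert row["rank_nodal_efficiency"] == 1.0

    def test_complete_network_all_tied(self, complete12):
        t = metric_table(complete12)
        assert np.allclose(t.frame["rank_degree"], 6.5)
        assert np.allclose(t.frame["rank_nodal_efficiency"], 6.5)

    def test_empty_network(self, empty12):
        t = metric_table(empty12)
        assert (t.frame["degree"] == 0).all()
        assert t.global_efficiency == 0.0

    def test_csv_round_trip(self, star12, tmp_path):
        import pandas as pd

        t = metric_table(star12)
        path = tmp_path / "metrics.csv"
        t.write_csv(path)
        back = pd.read_csv(path)
        assert list(back["node"]) == list(star12.nodes)
        assert back["betweenness"].max() == pytest.approx(55.0)


class TestCompareGroupMetrics:
    def test_identical_networks_h_zero(self, star12):
        tables = [metric_table(star12), metric_table(star12)]
        res = compare_group_metrics(tables, "degree")
        assert res.omnibus.statistic == pytest.approx(0.0)

    def test_complete_vs_empty_separation(self, complete12, empty12):
        res = compare_group_metrics(
            [metric_table(empty12), metric_table(complete12)], "degree", alpha=1.1
        )
        (pair,) = res.pairwise.values()
        assert pair.statistic == 0.0  # empty network's U: no degree exceeds any

    def test_unknown_metric(self, star12):
        with pytest.raises(KeyError):
            compare_group_metrics([metric_table(star12)] * 2, "pagerank")

    def test_min_tables(self, star12):
        with pytest.raises(FosnetError):
            compare_group_metrics([metric_table(star12)], "degree")
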