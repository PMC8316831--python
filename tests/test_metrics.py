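import numpy as np
import pytest

from synnet.errors import ValidationError
from synnet.metrics import (
    average_path_length,
    clustering,
    compute_metrics_row,
    degree_stats,
    density_centralization,
)
from synnet.network import SyntacticNetwork
from synnet.treebank import CorpusMeta

from tests.conftest import random_network
from tests.oracles import (
    direct_centralization,
    direct_degrees,
    direct_density,
    enumeration_clustering,
    floyd_warshall_L,
)


def net_from(*edges, vertices=()):
    return SyntacticNetwork.from_edges(edges, vertices=vertices)


@pytest.fixture
def triangle():
    return net_from(("a", "b"), ("b", "c"), ("a", "c"))


class TestDegreeStats:
    def test_toy_degrees(self, toy_network):
        stats = degree_stats(toy_network)
        assert stats.degrees["Kan"] == 3
        assert stats.degrees["Zai"] == 2
        assert stats.k_max == 3

    def test_toy_mean_degree(self, toy_network):
        # 4 merged edges over 5 vertices -> sum of degrees 8
        assert degree_stats(toy_network).k_mean == pytest.approx(8 / 5)

    def test_single_edge(self):
        assert degree_stats(net_from(("a", "b"))).k_mean == pytest.approx(1.0)

    def test_multiplicity_ignored(self, toy_network):
        # Ta-Kan has multiplicity 2 but contributes degree 1 to Ta
        assert degree_stats(toy_network).degrees["Ta"] == 1

    def test_handshake(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            net = random_network(rng)
            assert sum(degree_stats(net).degrees.values()) == 2 * net.M


class TestAveragePathLength:
    def test_toy_geodesics(self, toy_network):
        ps = average_path_length(toy_network)
        assert ps.distance("Ta", "Zai") == 2
        assert ps.distance("Shu", "Xuexiao") == 3

    def test_toy_mean(self, toy_network):
        assert average_path_length(toy_network).L == pytest.approx(18 / 10)

    def test_path_graph(self):
        net = net_from(("a", "b"), ("b", "c"))
        assert average_path_length(net).L == pytest.approx(4 / 3)

    def test_no_edges_errors(self):
        net = SyntacticNetwork()
        net.add_vertex("a")
        net.add_vertex("b")
        with pytest.raises(ValidationError, match="no edges"):
            average_path_length(net)

    def test_disconnected_reachable_mode(self):
        net = net_from(("a", "b"), ("c", "d"))
        ps = average_path_length(net)
        assert ps.L == pytest.approx(1.0)
        assert ps.reachable_pairs == 2
        assert ps.unreachable_pairs == 4
        assert ps.component_count == 2
        assert ps.largest_component_fraction == pytest.approx(0.5)

    def test_disconnected_all_pairs_errors(self):
        net = net_from(("a", "b"), ("c", "d"))
        with pytest.raises(ValidationError, match="disconnected"):
            average_path_length(net, mode="all-pairs")

    def test_largest_component_mode(self):
        net = net_from(("a", "b"), ("b", "c"), ("x", "y"))
        ps = average_path_length(net, mode="largest-component")
        assert ps.L == pytest.approx(4 / 3)

    def test_connected_modes_agree(self, toy_network):
        assert average_path_length(toy_network).L == pytest.approx(
            average_path_length(toy_network, mode="all-pairs").L
        )


class TestClustering:
    def test_toy_zero(self, toy_network):
        assert clustering(toy_network).C == 0.0

    def test_triangle(self, triangle):
        assert clustering(triangle).C == pytest.approx(1.0)

    def test_triangle_plus_pendant(self, triangle):
        triangle.add_edge("c", "d")
        # C_a = C_b = 1, C_c = 1/3, C_d = 0
        assert clustering(triangle).C == pytest.approx((1 + 1 + 1 / 3 + 0) / 4)

    def test_low_degree_vertices_count_as_zero(self):
        net = net_from(("a", "b"))
        net.add_vertex("isolated")
        stats = clustering(net)
        assert stats.local == {"a": 0.0, "b": 0.0, "isolated": 0.0}
        assert stats.C == 0.0

    def test_neighbor_edge_counts(self, triangle):
        assert clustering(triangle).neighbor_edges == {"a": 1, "b": 1, "c": 1}


class TestDensityCentralization:
    def test_toy_density(self, toy_network):
        assert density_centralization(toy_network).ND == pytest.approx(0.4)

    def test_toy_centralization_exact(self, toy_network):
        stats = density_centralization(toy_network)
        assert stats.NC == pytest.approx((5 / 4) * (3 / 4 - 0.4))

    def test_complete_graph(self):
        k4 = net_from(*[("abcd"[i], "abcd"[j]) for i in range(4) for j in range(i + 1, 4)])
        stats = density_centralization(k4)
        assert stats.ND == pytest.approx(1.0)
        assert stats.NC == pytest.approx(0.0)

    def test_approximate_form(self, toy_network):
        stats = density_centralization(toy_network, form="approximate")
        assert stats.NC == pytest.approx(3 / 5 - 0.4)
        assert stats.form_used == "approximate"

    def test_exact_vs_approximate_converge(self):
        rng = np.random.default_rng(11)
        from synnet.baselines import generate_gnm

        net = generate_gnm(600, 2400, seed=rng)
        exact = density_centralization(net).NC
        approx = density_centralization(net, form="approximate").NC
        assert abs(exact - approx) < 0.01

    def test_too_small_errors(self):
        net = SyntacticNetwork()
        net.add_vertex("a")
        with pytest.raises(ValidationError):
            density_centralization(net)


class TestOracleEquivalence:
    """Cross-check against brute-force references on random small graphs."""

    def test_fifty_random_graphs(self):
        rng = np.random.default_rng(123)
        for _ in range(50):
            net = random_network(rng)
            assert degree_stats(net).degrees == direct_degrees(net)
            assert average_path_length(net).L == pytest.approx(
                floyd_warshall_L(net), abs=1e-12
            )
            assert clustering(net).C == pytest.approx(
                enumeration_clustering(net), abs=1e-12
            )
            assert density_centralization(net).ND == pytest.approx(
                direct_density(net), abs=1e-12
            )
            assert density_centralization(net).NC == pytest.approx(
                direct_centralization(net), abs=1e-12
            )

    def test_networkx_cross_check(self):
        nx = pytest.importorskip("networkx")
        rng = np.random.default_rng(7)
        for _ in range(20):
            net = random_network(rng)
            g = nx.Graph()
            g.add_nodes_from(net.vertices)
            g.add_edges_from(uv for uv, _ in net.edges())
            assert clustering(net).C == pytest.approx(
                nx.average_clustering(g, count_zeros=True), abs=1e-12
            )
            if nx.is_connected(g):
                assert average_path_length(net).L == pytest.approx(
                    nx.average_shortest_path_length(g), abs=1e-12
                )


class TestMonotonicity:
    def test_adding_edge_never_hurts(self):
        rng = np.random.default_rng(99)
        for _ in range(10):
            net = random_network(rng, max_n=12)
            missing = [
                (u, v)
                for i, u in enumerate(net.vertices)
                for v in net.vertices[i + 1 :]
                if not net.has_edge(u, v)
            ]
            if not missing:
                continue
            before_nd = density_centralization(net).ND
            # compare L on the same reachable-pair set: restrict to graphs
            # that are already connected so the pair set cannot grow
            ps_before = average_path_length(net)
            u, v = missing[int(rng.integers(len(missing)))]
            net.add_edge(u, v)
            assert density_centralization(net).ND >= before_nd
            if ps_before.unreachable_pairs == 0:
                assert average_path_length(net).L <= ps_before.L + 1e-12


class TestMetricsRow:
    def test_toy_row(self, toy_network):
        meta = CorpusMeta(modality="written", level=1, label="toy")
        row = compute_metrics_row(toy_network, meta, token_count=8)
        assert row.N == 5
        assert row.M == 4
        assert row.C == 0.0
        assert row.ND == pytest.approx(0.4)
        assert row.gamma_prime is None

    def test_determinism(self, toy_network):
        meta = CorpusMeta(label="toy")
        assert compute_metrics_row(toy_network, meta) == compute_metrics_row(
            toy_network, meta
        )

    def test_fit_columns_filled(self, toy_network):
        class DummyFit:
            gamma_prime = 1.5
            R2 = 0.95

        row = compute_metrics_row(toy_network, CorpusMeta(), fit=DummyFit())
        assert row.gamma_prime == 1.5
        assert row.fit_R2 == 0.95
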