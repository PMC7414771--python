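"""Global graph measures against closed forms and brute-force oracles."""

import numpy as np
import pytest

from conftest import (
    bf_clustering,
    bf_local_efficiency,
    bf_modularity,
    exhaustive_max_q,
    random_weighted_graph,
)
from scnet.metrics import (
    FAST_SA,
    SAParams,
    avg_shortest_path_length,
    distance_matrix,
    global_measures,
    local_efficiency,
    maximize_modularity_sa,
    modularity_q,
    small_worldness,
    weight_permuted_nulls,
    weighted_clustering,
)
from scnet.network import build_network


def complete_graph(n, weight=1.0):
    w = np.full((n, n), weight)
    np.fill_diagonal(w, 0.0)
    return w


def two_cliques(k=4):
    w = np.zeros((2 * k, 2 * k))
    w[:k, :k] = 1.0
    w[k:, k:] = 1.0
    np.fill_diagonal(w, 0.0)
    return w


class TestShortestPaths:
    def test_path_with_inverse_weight_lengths(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 0.5
        w[1, 2] = w[2, 1] = 0.5
        # distances 2, 2, 4 -> mean 8/3
        assert avg_shortest_path_length(w) == pytest.approx(8 / 3)

    def test_complete_unit_graph(self):
        assert avg_shortest_path_length(complete_graph(6)) == pytest.approx(1.0)

    def test_disconnected_pairs_excluded(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 0.25
        assert avg_shortest_path_length(w) == pytest.approx(4.0)

    def test_no_reachable_pair_rejected(self):
        with pytest.raises(ValueError, match="reachable"):
            avg_shortest_path_length(np.zeros((4, 4)))


class TestClusteringAndEfficiency:
    def test_triangle_clustering_is_one(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 0.9
        w[0, 2] = w[2, 0] = 0.2
        w[1, 2] = w[2, 1] = 0.55
        c, avg = weighted_clustering(w)
        assert np.allclose(c, 1.0)
        assert avg == pytest.approx(1.0)

    def test_star_has_no_triangles(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 0.8
        w[0, 2] = w[2, 0] = 0.6
        c, avg = weighted_clustering(w)
        assert np.allclose(c, 0.0) and avg == 0.0

    def test_path_local_efficiency_hand_value(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 1.0
        w[1, 2] = w[2, 1] = 1.0
        e, avg = local_efficiency(w)
        assert e[1] == pytest.approx(0.5)  # d(A,C)=2 through the center
        assert avg == pytest.approx(1 / 6)

    def test_matches_brute_force_oracles(self, rng):
        for _ in range(300):
            n = int(rng.integers(3, 7))
            w = random_weighted_graph(rng, n)
            c, _ = weighted_clustering(w)
            e, _ = local_efficiency(w)
            assert np.allclose(c, bf_clustering(w), atol=1e-12)
            assert np.allclose(e, bf_local_efficiency(w), atol=1e-12)

    def test_neighborhood_subgraph_convention_differs_when_shortcut_exists(self):
        # path A-B-C: the full-network d(A,C) routes through B itself, which
        # the neighbourhood-subgraph convention forbids
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 1.0
        w[1, 2] = w[2, 1] = 1.0
        full, _ = local_efficiency(w, convention="full_network")
        sub, _ = local_efficiency(w, convention="neighborhood_subgraph")
        assert full[1] == pytest.approx(0.5)
        assert sub[1] == 0.0


class TestNullsAndSmallWorldness:
    def test_nulls_preserve_topology_and_weight_multiset(self, rng):
        w = random_weighted_graph(rng, 10)
        for m in weight_permuted_nulls(w, n_null=20, seed=1):
            assert np.array_equal(m > 0, w > 0)
            assert np.allclose(
                np.sort(m[np.triu_indices(10, 1)]),
                np.sort(w[np.triu_indices(10, 1)]),
            )

    def test_equal_weights_give_sw_exactly_one(self):
        assert small_worldness(complete_graph(8, 0.7), n_null=5, seed=0) == 1.0

    def test_exchangeable_weights_give_sw_near_one(self):
        # i.i.d. weights on a complete graph: the null reproduces the process
        rng = np.random.default_rng(5)
        vals = []
        for k in range(100):
            w = np.triu(rng.uniform(0.2, 1.0, (8, 8)), 1)
            w = w + w.T
            np.fill_diagonal(w, 0.0)
            vals.append(small_worldness(w, n_null=20, seed=k))
        assert abs(np.mean(vals) - 1.0) < 0.05

    def test_clustered_bridge_network_exceeds_one(self):
        w = two_cliques(5) * 0.6
        w[4, 5] = w[5, 4] = 0.95  # strong bridge
        assert small_worldness(w, n_null=100, seed=3) > 1.0


class TestModularity:
    def test_single_module_complete_triangle_is_zero(self):
        assert modularity_q(complete_graph(3), [0, 0, 0]) == pytest.approx(0.0)

    def test_two_cliques_natural_partition(self):
        q = modularity_q(two_cliques(), [0] * 4 + [1] * 4)
        assert q == pytest.approx(0.5)

    def test_singleton_partition_negative(self, rng):
        w = random_weighted_graph(rng, 6)
        s = w.sum(axis=1)
        expected = -np.sum((s / s.sum()) ** 2)
        assert modularity_q(w, np.arange(6)) == pytest.approx(expected, abs=1e-12)

    def test_matches_brute_force_for_random_partitions(self, rng):
        for _ in range(200):
            n = int(rng.integers(3, 7))
            w = random_weighted_graph(rng, n)
            labels = rng.integers(0, 3, n)
            assert modularity_q(w, labels) == pytest.approx(
                bf_modularity(w, labels), abs=1e-12
            )


class TestSimulatedAnnealing:
    def test_recovers_two_clique_partition(self):
        labels, q = maximize_modularity_sa(two_cliques(), seed=0)
        assert q == pytest.approx(0.5, abs=1e-12)
        assert len(set(labels[:4])) == 1 and len(set(labels[4:])) == 1
        assert set(labels[:4]) != set(labels[4:])

    def test_complete_graph_optimum_is_single_module(self):
        labels, q = maximize_modularity_sa(complete_graph(5), seed=1)
        assert q == pytest.approx(exhaustive_max_q(complete_graph(5)), abs=1e-9)
        assert q == pytest.approx(0.0, abs=1e-12)

    def test_never_below_trivial_partitions(self, rng):
        for k in range(10):
            w = random_weighted_graph(rng, 7)
            _, q = maximize_modularity_sa(w, sa_params=FAST_SA, seed=k)
            s = w.sum(axis=1)
            assert q >= 0.0 - 1e-12
            assert q >= -np.sum((s / s.sum()) ** 2) - 1e-12

    def test_bit_reproducible_for_fixed_seed(self, rng):
        w = random_weighted_graph(rng, 12)
        a = maximize_modularity_sa(w, sa_params=FAST_SA, seed=33)
        b = maximize_modularity_sa(w, sa_params=FAST_SA, seed=33)
        assert np.array_equal(a[0], b[0]) and a[1] == b[1]

    def test_invalid_schedule_rejected(self):
        with pytest.raises(ValueError):
            SAParams(cooling=1.5)
        with pytest.raises(ValueError):
            SAParams(t0=1e-6, tmin=1e-5)


class TestGlobalMeasures:
    def test_complete_unit_graph_closed_form(self):
        m = global_measures(complete_graph(6), n_null=10, seed=0)
        assert m.as_vector() == pytest.approx([1.0, 1.0, 1.0, 1.0, 0.0])

    def test_weight_scaling_invariances(self, rng):
        w = random_weighted_graph(rng, 9, density=0.7)
        c = 0.35
        m1 = global_measures(w, n_null=30, sa_params=FAST_SA, seed=4)
        m2 = global_measures(c * w, n_null=30, sa_params=FAST_SA, seed=4)
        assert m2.avgLCC == pytest.approx(m1.avgLCC, rel=1e-9)
        assert m2.Q == pytest.approx(m1.Q, abs=1e-9)
        assert m2.SW == pytest.approx(m1.SW, rel=1e-9)
        assert m2.avgSPL == pytest.approx(m1.avgSPL / c, rel=1e-9)
        assert m2.avgLEFF == pytest.approx(m1.avgLEFF * c, rel=1e-9)

    def test_measures_lie_in_their_ranges(self, rng):
        for k in range(20):
            w = random_weighted_graph(rng, 8, density=0.6)
            m = global_measures(w, n_null=10, sa_params=FAST_SA, seed=k)
            assert 0.0 <= m.avgLCC <= 1.0
            assert 0.0 <= m.avgLEFF <= 1.0
            assert m.Q <= 1.0
            assert m.avgSPL > 0

    def test_measure_subset_skips_the_rest(self):
        m = global_measures(
            complete_graph(5), n_null=5, seed=0, measures=("avgSPL", "avgLCC")
        )
        assert np.isnan(m.SW) and np.isnan(m.Q) and np.isnan(m.avgLEFF)
        assert m.avgSPL == pytest.approx(1.0)

    def test_distance_matrix_symmetry_and_triangle_inequality(self, rng):
        w = random_weighted_graph(rng, 10, density=0.4)
        d = distance_matrix(w)
        assert np.allclose(d, d.T)
        finite = np.isfinite(d)
        for i in range(10):
            for j in range(10):
                for k in range(10):
                    if finite[i, k] and finite[k, j]:
                        assert d[i, j] <= d[i, k] + d[k, j] + 1e-9
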