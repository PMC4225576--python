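import itertools
import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from vitisnet.netbuild import (
    CorrelationNetwork,
    bh_adjust,
    build_network,
    correlation_qvalues,
    density_from_counts,
    network_from_matrix,
    network_stats,
    nodes_from_degree,
    pairwise_correlations,
    parameter_from_adjacency,
    adjacency_from_matrix,
)


def brute_bh(p):
    """Step-up BH by direct enumeration of the adjusted values."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


def pearson_by_formula(x, y):
    """Product-moment r and its two-sided t-transform p, from scratch."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = len(x)
    xm, ym = x - x.mean(), y - y.mean()
    r = (xm * ym).sum() / math.sqrt((xm**2).sum() * (ym**2).sum())
    t = r * math.sqrt((n - 2) / (1 - r**2))
    p = 2 * stats.t.sf(abs(t), n - 2)
    return r, p


class TestPairwiseCorrelations:
    def test_self_and_negation(self):
        x = np.array([1.0, 2.0, 4.0, 8.0, 9.0])
        df = pd.DataFrame({"a": x, "b": x, "c": -x})
        res = pairwise_correlations(df)
        assert res.r.loc["a", "b"] == pytest.approx(1.0)
        assert res.r.loc["a", "c"] == pytest.approx(-1.0)
        assert res.p.loc["a", "b"] == res.p.loc["a", "c"] == 0.0

    def test_five_point_pair_matches_formula_oracle(self):
        x = [1.0, 2.0, 3.0, 5.0, 8.0]
        y = [2.0, 1.0, 4.0, 4.0, 9.0]
        res = pairwise_correlations(pd.DataFrame({"x": x, "y": y}))
        r_hand, p_hand = pearson_by_formula(x, y)
        assert res.r.loc["x", "y"] == pytest.approx(r_hand, abs=1e-10)
        assert res.p.loc["x", "y"] == pytest.approx(p_hand, abs=1e-10)
        assert res.n.loc["x", "y"] == 5

    def test_pairwise_complete_and_min_pairs(self):
        df = pd.DataFrame(
            {
                "a": [1.0, 2, 3, 4, 5, 6],
                "b": [2.0, 4, 6, 8, 10, 12],
                "c": [1.0, 2, np.nan, np.nan, np.nan, 3],
            }
        )
        res = pairwise_correlations(df, min_pairs=4)
        assert res.n.loc["a", "c"] == 3
        assert math.isnan(res.r.loc["a", "c"])  # below min_pairs: a non-test
        assert res.r.loc["a", "b"] == pytest.approx(1.0)

    def test_zero_variance_column_undefined(self):
        df = pd.DataFrame({"a": [1.0, 2, 3, 4], "flat": [5.0, 5, 5, 5]})
        res = pairwise_correlations(df)
        assert math.isnan(res.r.loc["a", "flat"])
        assert math.isnan(res.p.loc["a", "flat"])


class TestCorrelationQvalues:
    def test_single_pair_q_equals_p(self):
        p = pd.DataFrame([[np.nan, 0.03], [0.03, np.nan]], columns=["a", "b"], index=["a", "b"])
        q = correlation_qvalues(p)
        assert q.loc["a", "b"] == pytest.approx(0.03)

    def test_identical_ps_are_a_fixed_point(self):
        n = 4
        arr = np.full((n, n), 0.2)
        np.fill_diagonal(arr, np.nan)
        q = correlation_qvalues(arr)
        iu = np.triu_indices(n, 1)
        np.testing.assert_allclose(q[iu], 0.2)

    def test_six_pair_toy_matches_brute_stepup(self):
        ps = np.array([0.001, 0.04, 0.011, 0.3, 0.9, 0.02])
        arr = np.full((4, 4), np.nan)
        iu = np.triu_indices(4, 1)
        arr[iu] = ps
        arr.T[iu] = ps
        q = correlation_qvalues(arr)
        np.testing.assert_allclose(q[iu], brute_bh(ps), atol=1e-14)

    @given(st.lists(st.floats(min_value=1e-12, max_value=1.0), min_size=1, max_size=40))
    def test_bh_matches_enumeration_and_bounds(self, ps):
        ps = np.asarray(ps)
        q = bh_adjust(ps)
        np.testing.assert_allclose(q, brute_bh(ps), atol=1e-12)
        assert (q >= ps - 1e-15).all() and (q <= 1.0 + 1e-15).all()
        # monotone in the p-order
        order = np.argsort(ps)
        assert (np.diff(q[order]) >= -1e-15).all()

    def test_undefined_pairs_stay_undefined_and_out_of_m(self):
        arr = np.full((3, 3), np.nan)
        arr[0, 1] = arr[1, 0] = 0.01
        q = correlation_qvalues(arr)
        assert q[0, 1] == pytest.approx(0.01)  # m = 1, not 3
        assert math.isnan(q[0, 2])


class TestBuildNetwork:
    def test_independent_noise_gives_zero_node_network(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(size=(24, 20)))
        df.columns = [f"m{i}" for i in range(20)]
        net = network_from_matrix(df)
        assert net.n_edges == 0 and net.n_nodes == 0
        assert not net.viable

    def test_duplicated_column_yields_single_perfect_edge(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=24)
        df = pd.DataFrame({"a": x, "b": x, "c": rng.normal(size=24), "d": rng.normal(size=24)})
        net = network_from_matrix(df)
        assert net.edge_set() == {("a", "b")}
        assert net.graph.edges["a", "b"]["r"] == pytest.approx(1.0)

    def test_block_toy_matches_brute_force_threshold_scan(self):
        rng = np.random.default_rng(3)
        latent = rng.normal(size=30)
        block = 0.97**0.5 * latent[:, None] + (1 - 0.97) ** 0.5 * rng.normal(size=(30, 4))
        noise = rng.normal(size=(30, 4))
        df = pd.DataFrame(np.hstack([block, noise]), columns=[f"m{i}" for i in range(8)])
        net = network_from_matrix(df, r_min=0.9, q_max=0.01)
        # brute force: all 28 pairs, direct formula + brute BH + scan
        cols = list(df.columns)
        pairs = list(itertools.combinations(range(8), 2))
        rs, ps = zip(*(pearson_by_formula(df.iloc[:, i], df.iloc[:, j]) for i, j in pairs))
        qs = brute_bh(np.array(ps))
        expected = {
            (cols[i], cols[j])
            for (i, j), r, q in zip(pairs, rs, qs)
            if r >= 0.9 and q <= 0.01
        }
        assert net.edge_set() == expected

    def test_sign_mode_absolute_admits_negative_edges(self):
        x = np.array([1.0, 2, 3, 4, 5, 6, 7, 8.0])
        df = pd.DataFrame({"a": x, "b": -x + 0.0, "c": np.r_[x[1:], 2.0]})
        pos = network_from_matrix(df, sign_mode="positive")
        neg = network_from_matrix(df, sign_mode="absolute")
        assert ("a", "b") not in pos.edge_set()
        assert ("a", "b") in neg.edge_set()

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(4)
        latent = rng.normal(size=24)
        df = pd.DataFrame(
            0.8 * latent[:, None] + 0.4 * rng.normal(size=(24, 10)),
            columns=[f"m{i}" for i in range(10)],
        )
        corr = pairwise_correlations(df)
        q = correlation_qvalues(corr.p)
        prev = None
        for r_min in (0.3, 0.5, 0.7, 0.9):
            edges = build_network(corr.r, q, r_min=r_min, q_max=0.05).edge_set()
            if prev is not None:
                assert edges <= prev
            prev = edges
        loose = build_network(corr.r, q, r_min=0.5, q_max=0.05).edge_set()
        tight = build_network(corr.r, q, r_min=0.5, q_max=0.001).edge_set()
        assert tight <= loose


class TestNetworkStats:
    def test_complete_graph(self):
        net = CorrelationNetwork(nx.complete_graph(4))
        s = network_stats(net)
        assert (s.n_nodes, s.n_edges) == (4, 6)
        assert s.avg_degree == pytest.approx(3.0)
        assert s.density == pytest.approx(1.0)
        assert s.clustering == pytest.approx(1.0)
        assert s.diameter == 1

    def test_star_graph(self):
        s = network_stats(CorrelationNetwork(nx.star_graph(4)))
        assert s.clustering == pytest.approx(0.0)
        assert s.diameter == 2

    def test_empty_network_statistics_undefined_not_zero(self):
        s = network_stats(CorrelationNetwork(nx.Graph()))
        assert s.n_nodes == 0 and s.n_edges == 0
        for value in (s.avg_degree, s.density, s.clustering, s.diameter):
            assert math.isnan(value)

    def test_density_equals_avg_degree_over_n_minus_one(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            g = nx.gnp_random_graph(12, 0.3, seed=int(rng.integers(1e6)))
            g.remove_nodes_from(list(nx.isolates(g)))
            if g.number_of_edges() == 0:
                continue
            s = network_stats(g)
            assert s.density == pytest.approx(s.avg_degree / (s.n_nodes - 1))

    def test_diameter_on_largest_component(self):
        g = nx.Graph([("a", "b"), ("b", "c"), ("c", "d"), ("x", "y")])
        s = network_stats(g)
        assert s.diameter == 3 and s.largest_component == 4


class TestPublishedTableUtilities:
    def test_node_count_and_density_from_edges_and_degree(self):
        assert nodes_from_degree(870, 22.6) == 77
        assert density_from_counts(870, 77) == pytest.approx(0.297, abs=5e-3)


class TestAdjacencyFastPath:
    def test_fast_path_agrees_with_dataframe_route(self):
        rng = np.random.default_rng(6)
        latent = rng.normal(size=24)
        X = 0.95**0.5 * latent[:, None] + 0.05**0.5 * rng.normal(size=(24, 8))
        X = np.hstack([X, rng.normal(size=(24, 6))])
        df = pd.DataFrame(X, columns=[f"m{i}" for i in range(14)])
        net = network_from_matrix(df, r_min=0.9, q_max=0.01)
        adj = adjacency_from_matrix(X, 0.9, 0.01)
        idx = {name: i for i, name in enumerate(df.columns)}
        fast_edges = {
            tuple(sorted((f"m{i}", f"m{j}")))
            for i in range(14)
            for j in range(i + 1, 14)
            if adj[i, j]
        }
        assert fast_edges == net.edge_set()
        density, n_nodes = parameter_from_adjacency(adj, "density")
        s = network_stats(net)
        assert density == pytest.approx(s.density) and n_nodes == s.n_nodes
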