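import itertools
import math

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.sparse.csgraph import floyd_warshall

import interoscore as ic
from interoscore import topology as T

from conftest import random_simple_graph


def path_graph(n):
    g = nx.Graph()
    g.add_edges_from((f"p{i}", f"p{i+1}") for i in range(n - 1))
    return g


def brute_force_metrics(g):
    """Floyd-Warshall / enumeration oracle for diameter, transitivity, efficiency."""
    nodes = sorted(g.nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    adj = np.zeros((n, n))
    for a, b in g.edges:
        adj[idx[a], idx[b]] = adj[idx[b], idx[a]] = 1
    dist = floyd_warshall(adj, unweighted=True)
    finite = dist[np.isfinite(dist)]
    comp = max(nx.connected_components(g), key=len) if g.number_of_edges() else set()
    comp_idx = [idx[v] for v in comp]
    diam = int(dist[np.ix_(comp_idx, comp_idx)].max()) if comp_idx else None
    triangles = sum(
        1
        for a, b, c in itertools.combinations(nodes, 3)
        if g.has_edge(a, b) and g.has_edge(b, c) and g.has_edge(a, c)
    )
    triples = sum(math.comb(d, 2) for _, d in g.degree())
    trans = 3 * triangles / triples if triples else 0.0
    eff = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            if np.isfinite(dist[i, j]) and dist[i, j] > 0:
                eff += 1.0 / dist[i, j]
    eff /= n * (n - 1) / 2 if n > 1 else 1
    return diam, trans, eff


graph_strategy = st.builds(
    random_simple_graph,
    n_nodes=st.integers(min_value=4, max_value=40),
    n_edges=st.integers(min_value=3, max_value=80),
    seed=st.integers(min_value=0, max_value=10_000),
)


class TestDegreeDistribution:
    def test_triangle(self):
        g = nx.complete_graph(3)
        assert T.degree_distribution(g) == {2: 1.0}

    def test_star(self):
        g = nx.star_graph(3)
        assert T.degree_distribution(g) == {1: 0.75, 3: 0.25}

    def test_matches_direct_tally(self):
        g = ic.generate_scale_free(300, 2.5, seed=7)
        dist = T.degree_distribution(g)
        assert sum(dist.values()) == pytest.approx(1.0)
        tally = {}
        for _, k in g.degree():
            tally[k] = tally.get(k, 0) + 1
        assert dist == {k: c / g.number_of_nodes() for k, c in tally.items()}


class TestPowerLawFit:
    def test_exact_power_law_recovered(self):
        dist = {k: k**-2.0 for k in range(1, 51)}
        z = sum(dist.values())
        fit = T.fit_power_law({k: p / z for k, p in dist.items()})
        assert fit.exponent == pytest.approx(2.0, abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0)

    def test_uniform_distribution_flat(self):
        fit = T.fit_power_law({k: 0.1 for k in range(1, 11)})
        assert fit.exponent == pytest.approx(0.0, abs=1e-9)

    def test_too_few_points_is_domain_error(self):
        with pytest.raises(ValueError):
            T.fit_power_law({1: 0.5, 2: 0.5})

    def test_configuration_model_recovery(self):
        g = ic.generate_scale_free(5000, 2.5, seed=11)
        dist = T.degree_distribution(g)
        fit = T.fit_power_law(dist, min_probability=10 / g.number_of_nodes())
        assert fit.exponent == pytest.approx(2.5, abs=0.3)


class TestDiameter:
    def test_path(self):
        assert T.diameter(path_graph(7)) == 6

    def test_complete(self):
        assert T.diameter(nx.complete_graph(5)) == 1

    def test_edgeless_is_domain_error(self):
        g = nx.Graph()
        g.add_nodes_from("abc")
        with pytest.raises(ValueError):
            T.diameter(g)

    def test_random_graph_matches_floyd_warshall(self):
        g = random_simple_graph(30, 45, seed=3)
        diam, _, _ = brute_force_metrics(g)
        assert T.diameter(g) == diam


class TestClustering:
    def test_triangle(self):
        assert T.clustering_coefficient(nx.complete_graph(3)) == pytest.approx(1.0)

    def test_star_is_triangle_free(self):
        assert T.clustering_coefficient(nx.star_graph(5)) == 0.0

    def test_k4_by_hand_enumeration(self):
        # K4: 4 triangles, 12 connected triples -> 3*4/12 = 1
        g = nx.complete_graph(4)
        _, trans, _ = brute_force_metrics(g)
        assert trans == pytest.approx(1.0)
        assert T.clustering_coefficient(g) == pytest.approx(1.0)


class TestGlobalEfficiency:
    def test_complete_graph(self):
        assert T.global_efficiency(nx.complete_graph(6)) == pytest.approx(1.0)

    def test_path_of_three(self):
        assert T.global_efficiency(path_graph(3)) == pytest.approx((1 + 1 + 0.5) / 3)

    def test_disconnected_pair(self):
        g = nx.Graph()
        g.add_nodes_from(["a", "b"])
        assert T.global_efficiency(g) == 0.0

    def test_subset_distances_use_full_network(self):
        # a-b-c: the pair {a, c} is connected only through b
        g = path_graph(3)
        assert T.global_efficiency(g, ["p0", "p2"]) == pytest.approx(0.5)

    @given(graph_strategy, st.integers(min_value=0, max_value=1000))
    @settings(max_examples=25)
    def test_monotone_under_edge_addition(self, g, seed):
        import random

        rng = random.Random(seed)
        nodes = sorted(g.nodes)
        before = T.global_efficiency(g)
        a, b = rng.sample(nodes, 2)
        g2 = g.copy()
        g2.add_edge(a, b)
        assert T.global_efficiency(g2) >= before - 1e-12


@given(graph_strategy)
@settings(max_examples=25)
def test_metric_oracle_equivalence_on_random_graphs(g):
    """diameter / clustering / efficiency agree with brute-force oracles (<= 40 nodes)."""
    diam, trans, eff = brute_force_metrics(g)
    if g.number_of_edges() > 0:
        assert T.diameter(g) == diam
    assert T.clustering_coefficient(g) == pytest.approx(trans)
    assert T.global_efficiency(g) == pytest.approx(eff)


class TestRewiring:
    def test_degree_sequence_preserved(self):
        g = random_simple_graph(50, 120, seed=9)
        r = T.rewire_full(g, seed=1)
        assert sorted(d for _, d in r.degree()) == sorted(d for _, d in g.degree())
        assert dict(r.degree()) == dict(g.degree())

    def test_same_seed_is_deterministic(self):
        g = random_simple_graph(40, 90, seed=2)
        assert set(T.rewire_full(g, seed=7).edges) == set(T.rewire_full(g, seed=7).edges)

    def test_rewiring_destroys_planted_triangles(self):
        broken = 0
        for seed in range(20):
            g = ic.generate_modular_known_predicted(120, 10, 0.6, 0.0, 0.01, seed)[0]
            before = T.clustering_coefficient(g)
            after = T.clustering_coefficient(T.rewire_full(g, seed=seed + 500))
            if after < before:
                broken += 1
        assert broken >= 18

    def test_partial_rewire_identity_without_predictions(self):
        gk = random_simple_graph(30, 60, seed=4)
        gp = nx.Graph()
        out = T.rewire_partial(gk, gp, seed=0)
        assert set(out.edges) == set(gk.edges)

    def test_partial_rewire_preserves_known_edges_and_predicted_degrees(self):
        gk, gp = ic.generate_modular_known_predicted(100, 5, 0.3, 0.2, 0.02, seed=3)
        out = T.rewire_partial(gk, gp, seed=5)
        known_edges = {ic.canonical_pair(a, b) for a, b in gk.edges}
        out_edges = {ic.canonical_pair(a, b) for a, b in out.edges}
        assert known_edges <= out_edges
        new_pred = out_edges - known_edges
        deg_new = {}
        for a, b in new_pred:
            deg_new[a] = deg_new.get(a, 0) + 1
            deg_new[b] = deg_new.get(b, 0) + 1
        deg_old = {v: d for v, d in gp.degree() if d}
        assert deg_new == deg_old


class TestRandomizeSameNodes:
    def test_preserves_nodes_and_edge_count(self):
        g = random_simple_graph(40, 70, seed=6)
        r = T.randomize_same_nodes(g, seed=1)
        assert set(r.nodes) == set(g.nodes)
        assert r.number_of_edges() == g.number_of_edges()

    def test_expected_clustering_near_density(self):
        # Erdos-Renyi: E[transitivity] ~ edge density
        n, m = 400, 2400
        g = random_simple_graph(n, m, seed=8)
        r = T.randomize_same_nodes(g, seed=2)
        density = 2 * m / (n * (n - 1))
        assert T.clustering_coefficient(r) == pytest.approx(density, abs=0.5 * density)


class TestEfficiencyZScore:
    def test_whole_network_is_exactly_zero(self):
        g = random_simple_graph(25, 50, seed=10)
        res = T.node_set_efficiency_zscore(g, sorted(g.nodes), n_samples=30, seed=0)
        assert res.z == 0.0
        assert not res.degenerate

    def test_planted_dense_module_scores_high(self):
        g = random_simple_graph(200, 300, seed=1)
        module = sorted(g.nodes)[:12]
        for a, b in itertools.combinations(module, 2):
            g.add_edge(a, b)
        res = T.node_set_efficiency_zscore(g, module, n_samples=1000, seed=5)
        assert res.z > 3
        assert res.p_empirical < 0.01

    def test_random_node_sets_are_calibrated(self):
        import random

        g = random_simple_graph(120, 240, seed=2)
        nodes = sorted(g.nodes)
        extreme = 0
        for trial in range(100):
            subset = random.Random(9000 + trial).sample(nodes, 10)
            res = T.node_set_efficiency_zscore(g, subset, n_samples=150, seed=trial)
            if abs(res.z) >= 3:
                extreme += 1
        assert extreme <= 5


class TestProportionTest:
    def test_null_gives_zero(self):
        t, p = T.proportion_test(25, 100, 0.25)
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_direct_formula_value(self):
        t, _ = T.proportion_test(150, 300, 0.25)
        assert t == pytest.approx(10.0)

    def test_sign_reflects_depletion(self):
        # an interactome under-representing orthologues: observed below genome rate
        t, p = T.proportion_test(40, 400, 0.20)
        assert t < 0
        assert p < 0.05

    def test_degenerate_proportion_is_domain_error(self):
        with pytest.raises(ValueError):
            T.proportion_test(1, 10, 0.0)
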