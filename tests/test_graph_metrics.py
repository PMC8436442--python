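"""Graph-metric correctness: closed forms, exhaustive oracles, invariances,
and the degree-preserving randomization."""

import networkx as nx
import numpy as np
import pytest

import wmconnect as wc
from wmconnect.graph_metrics import distance_matrix
from wmconnect.thresholding import ThresholdedNetwork

from . import oracles


def as_net(adj, weighted):
    adj = np.asarray(adj, dtype=float)
    if not weighted:
        adj = (adj > 0).astype(float)
    return ThresholdedNetwork(adjacency=adj, sparsity=0.5, weighted=weighted)


def complete_graph(n):
    return np.ones((n, n)) - np.eye(n)


def cycle_graph(n):
    a = np.zeros((n, n))
    for i in range(n):
        a[i, (i + 1) % n] = a[(i + 1) % n, i] = 1
    return a


def star_graph(n_leaves):
    a = np.zeros((n_leaves + 1, n_leaves + 1))
    a[0, 1:] = a[1:, 0] = 1
    return a


def path_graph(n):
    a = np.zeros((n, n))
    for i in range(n - 1):
        a[i, i + 1] = a[i + 1, i] = 1
    return a


# ---------------------------------------------------------------------------
# closed forms
# ---------------------------------------------------------------------------

class TestClosedForms:
    def test_complete_k4_clustering(self):
        _, cp = wc.clustering_coefficient(as_net(complete_graph(4), False))
        assert cp == pytest.approx(1.0)

    def test_path_p3_no_triangles(self):
        _, cp = wc.clustering_coefficient(as_net(path_graph(3), False))
        assert cp == 0.0

    def test_cycle_c5_path_metrics(self):
        lp, eglob, _, n_inf = wc.path_metrics(as_net(cycle_graph(5), False))
        assert lp == pytest.approx(1.5)
        assert eglob == pytest.approx(0.75)
        assert n_inf == 0

    def test_two_disjoint_k2_global_efficiency(self):
        a = np.zeros((4, 4))
        a[0, 1] = a[1, 0] = a[2, 3] = a[3, 2] = 1
        lp, eglob, _, n_inf = wc.path_metrics(as_net(a, False))
        assert eglob == pytest.approx(1 / 3)
        assert lp == pytest.approx(1.0)  # finite pairs only
        assert n_inf == 8

    def test_star_center_nodal_efficiency_and_betweenness(self):
        net = as_net(star_graph(4), False)
        _, _, eff, _ = wc.path_metrics(net)
        assert eff[0] == pytest.approx(1.0)
        bc = wc.betweenness(net)
        assert bc[0] == pytest.approx(6.0)  # (n-1)(n-2)/2 with n=5
        np.testing.assert_allclose(bc[1:], 0.0)

    def test_cycle_c4_betweenness_tie_split(self):
        bc = wc.betweenness(as_net(cycle_graph(4), False))
        np.testing.assert_allclose(bc, 0.5)

    def test_local_efficiency_complete_and_star(self):
        _, eloc = wc.local_efficiency(as_net(complete_graph(4), False))
        assert eloc == pytest.approx(1.0)
        _, eloc_star = wc.local_efficiency(as_net(star_graph(4), False))
        assert eloc_star == 0.0


# ---------------------------------------------------------------------------
# exhaustive oracle equivalence
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("weighted", [False, True], ids=["binary", "weighted"])
def test_oracle_equivalence_small_graphs(weighted):
    """All metrics match independent exhaustive implementations to 1e-9 on
    100 random graphs (binary and weighted) with <= 7 nodes."""
    rng = np.random.default_rng(42 + int(weighted))
    for trial in range(100):
        n = int(rng.integers(3, 8))
        adj = oracles.random_graph(rng, n, weighted=weighted, p=float(rng.uniform(0.3, 0.9)))
        net = as_net(adj, weighted)
        c, cp = wc.clustering_coefficient(net)
        np.testing.assert_allclose(
            c, oracles.brute_clustering(net.adjacency, weighted), atol=1e-9
        )
        lp, eglob, eff, _ = wc.path_metrics(net)
        o_lp, o_eglob, o_eff = oracles.brute_path_metrics(net.adjacency, weighted)
        if np.isfinite(o_lp):
            assert lp == pytest.approx(o_lp, abs=1e-9)
        np.testing.assert_allclose(eglob, o_eglob, atol=1e-9)
        np.testing.assert_allclose(eff, o_eff, atol=1e-9)
        np.testing.assert_allclose(
            wc.betweenness(net), oracles.brute_betweenness(net.adjacency, weighted),
            atol=1e-9,
        )
        el, _ = wc.local_efficiency(net)
        np.testing.assert_allclose(
            el, oracles.brute_local_efficiency(net.adjacency, weighted), atol=1e-9
        )


def test_degree_strength_conventions(rng):
    adj = oracles.random_graph(rng, 10, weighted=True, p=0.6)
    wnet = as_net(adj, True)
    bnet = as_net(adj, False)
    np.testing.assert_allclose(wc.degree(wnet), adj.sum(axis=1))
    np.testing.assert_allclose(wc.degree(bnet), (adj > 0).sum(axis=1))


def test_permutation_equivariance(rng):
    """Relabeling nodes permutes nodal metrics and leaves globals unchanged."""
    adj = oracles.random_graph(rng, 12, weighted=True, p=0.5)
    perm = rng.permutation(12)
    padj = adj[np.ix_(perm, perm)]
    net, pnet = as_net(adj, True), as_net(padj, True)
    c, cp = wc.clustering_coefficient(net)
    c2, cp2 = wc.clustering_coefficient(pnet)
    np.testing.assert_allclose(c2, c[perm], atol=1e-12)
    assert cp2 == pytest.approx(cp, abs=1e-12)
    lp, eg, eff, _ = wc.path_metrics(net)
    lp2, eg2, eff2, _ = wc.path_metrics(pnet)
    assert (lp2, eg2) == pytest.approx((lp, eg), abs=1e-12)
    np.testing.assert_allclose(eff2, eff[perm], atol=1e-12)


def test_weighted_distance_is_inverse_weight():
    a = np.zeros((3, 3))
    a[0, 1] = a[1, 0] = 0.5
    a[1, 2] = a[2, 1] = 0.25
    d = distance_matrix(as_net(a, True))
    assert d[0, 1] == pytest.approx(2.0)
    assert d[0, 2] == pytest.approx(6.0)


# ---------------------------------------------------------------------------
# random references and normalization
# ---------------------------------------------------------------------------

class TestRandomReference:
    def test_degree_sequence_preserved(self, rng):
        adj = oracles.random_graph(rng, 20, weighted=True, p=0.3)
        net = as_net(adj, True)
        deg = (adj > 0).sum(axis=1)
        for ref in wc.random_reference(net, n_rand=5, seed=1):
            np.testing.assert_array_equal((ref.adjacency > 0).sum(axis=1), deg)

    def test_weight_multiset_preserved(self, rng):
        adj = oracles.random_graph(rng, 15, weighted=True, p=0.4)
        net = as_net(adj, True)
        orig = np.sort(adj[np.triu_indices(15, 1)])
        for ref in wc.random_reference(net, n_rand=3, seed=2):
            np.testing.assert_allclose(
                np.sort(ref.adjacency[np.triu_indices(15, 1)]), orig, atol=1e-12
            )

    def test_zero_swaps_is_identity_topology(self, rng):
        adj = oracles.random_graph(rng, 10, weighted=False, p=0.5)
        net = as_net(adj, False)
        refs = wc.random_reference(net, n_rand=2, n_swaps_per_edge=0, seed=0)
        for ref in refs:
            np.testing.assert_array_equal(ref.binary, net.binary)

    def test_seed_determinism(self, rng):
        adj = oracles.random_graph(rng, 20, weighted=True, p=0.4)
        net = as_net(adj, True)
        a = wc.random_reference(net, n_rand=4, seed=9)
        b = wc.random_reference(net, n_rand=4, seed=9)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.adjacency, y.adjacency)

    def test_lattice_rewiring_lowers_clustering(self):
        g = nx.watts_strogatz_graph(40, 6, 0.0, seed=1)  # ring lattice
        adj = nx.to_numpy_array(g)
        net = as_net(adj, False)
        _, cp = wc.clustering_coefficient(net)
        refs = wc.random_reference(net, n_rand=20, seed=3)
        cp_refs = np.mean([wc.clustering_coefficient(r)[1] for r in refs])
        assert cp_refs < cp


class TestNormalizedGlobals:
    def test_self_normalization(self, rng):
        adj = oracles.random_graph(rng, 12, weighted=True, p=0.6)
        net = as_net(adj, True)
        gm = wc.normalized_globals(net, [net, net])
        assert gm.gamma == pytest.approx(1.0)
        assert gm.lam == pytest.approx(1.0)
        assert gm.sigma == pytest.approx(1.0)

    def test_sigma_identity(self, rng):
        adj = oracles.random_graph(rng, 15, weighted=True, p=0.5)
        net = as_net(adj, True)
        refs = wc.random_reference(net, n_rand=5, seed=4)
        gm = wc.normalized_globals(net, refs)
        assert gm.sigma == pytest.approx(gm.gamma / gm.lam, abs=1e-12)

    def test_small_world_backbone_sigma_above_criterion(self):
        bb = wc.generate_backbone(wc.SimulationConfig(seed=5))
        net = wc.apply_sparsity(bb.template, 0.2)
        assert wc.small_worldness(net, n_rand=10, seed=0) > 1.1

    def test_erdos_renyi_sigma_near_one(self):
        sigmas = []
        for seed in range(5):
            g = nx.gnp_random_graph(90, 0.2, seed=seed)
            net = as_net(nx.to_numpy_array(g), False)
            sigmas.append(wc.small_worldness(net, n_rand=5, seed=seed))
        assert np.mean(sigmas) == pytest.approx(1.0, abs=0.1)


def test_networkx_cross_check_binary(rng):
    """Binary Cp and Lp agree with the networkx reference implementations."""
    g = nx.gnp_random_graph(25, 0.3, seed=7)
    adj = nx.to_numpy_array(g)
    net = as_net(adj, False)
    _, cp = wc.clustering_coefficient(net)
    assert cp == pytest.approx(nx.average_clustering(g), abs=1e-12)
    if nx.is_connected(g):
        lp, eglob, _, _ = wc.path_metrics(net)
        assert lp == pytest.approx(nx.average_shortest_path_length(g), abs=1e-12)
        assert eglob == pytest.approx(nx.global_efficiency(g), abs=1e-12)


def test_nodal_auc_table_shape(small_cohort):
    grid = wc.SparsityGrid(0.20, 0.30, 0.05)
    tables = wc.nodal_auc_table(small_cohort, grid)
    assert set(tables) == {"degree", "betweenness", "efficiency"}
    for df in tables.values():
        assert len(df) == len(small_cohort)
        assert list(df.columns[2:]) == list(small_cohort.atlas.names)
        assert (df.iloc[:, 2:].to_numpy() >= 0).all()
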