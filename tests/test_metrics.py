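"""Graph-measure correctness against independent oracles and invariants."""

import numpy as np
import networkx as nx
import pytest
from hypothesis import given, settings, strategies as st

from lldnet.connectome import Connectome
from lldnet import metrics as mx
from conftest import random_connectome


# ---------------------------------------------------------------- oracles

def floyd_warshall_oracle(weights):
    """Plain triple-loop Floyd-Warshall on lengths 1/w."""
    n = weights.shape[0]
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for i in range(n):
        for j in range(n):
            if i != j and weights[i, j] > 0:
                d[i, j] = 1.0 / weights[i, j]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def onnela_oracle(weights, normalize):
    """Exhaustive enumeration of ordered neighbour pairs per node."""
    w = weights / weights.max() if normalize and weights.max() > 0 else weights
    n = w.shape[0]
    k = (w > 0).sum(axis=1)
    out = np.zeros(n)
    for i in range(n):
        if k[i] < 2:
            continue
        acc = 0.0
        for j in range(n):
            for h in range(n):
                if j != i and h != i and j != h:
                    acc += (w[i, j] * w[i, h] * w[j, h]) ** (1 / 3)
        out[i] = acc / (k[i] * (k[i] - 1))
    return out


# ------------------------------------------------------- worked examples

def test_degree_examples():
    assert mx.nodal_degree(Connectome(np.zeros((4, 4)), "abcd")).tolist() == [0] * 4
    comp = np.ones((4, 4)) - np.eye(4)
    assert mx.nodal_degree(Connectome(comp, "abcd")).tolist() == [3] * 4
    w = np.zeros((5, 5))
    for i, j in [(0, 1), (1, 2), (1, 3)]:
        w[i, j] = w[j, i] = 2.5
    assert mx.nodal_degree(Connectome(w, "abcde")).tolist() == [1, 3, 1, 1, 0]


def test_strength_examples(rng):
    tri = Connectome(2 * (np.ones((3, 3)) - np.eye(3)), "abc")
    np.testing.assert_allclose(mx.nodal_strength(tri), [4, 4, 4])
    assert mx.total_strength(tri) == 6.0
    conn = random_connectome(6, 0.6, rng)
    np.testing.assert_allclose(mx.nodal_strength(conn), conn.weights.sum(axis=1))
    np.testing.assert_allclose(
        mx.total_strength(conn), conn.weights[np.triu_indices(6, 1)].sum()
    )
    # total strength is half the summed nodal strength
    np.testing.assert_allclose(
        mx.total_strength(conn), mx.nodal_strength(conn).sum() / 2
    )


def test_edge_density_examples():
    comp = Connectome(np.ones((4, 4)) - np.eye(4), "abcd")
    assert mx.edge_density(comp) == 1.0
    assert mx.edge_density(Connectome(np.zeros((4, 4)), "abcd")) == 0.0
    path = np.zeros((4, 4))
    for i in range(3):
        path[i, i + 1] = path[i + 1, i] = 1.0
    assert mx.edge_density(Connectome(path, "abcd")) == 0.5
    with pytest.raises(ValueError, match="2 nodes"):
        mx.edge_density(Connectome(np.zeros((1, 1)), "a"))


def test_clustering_examples(triangle_unequal):
    unit_tri = Connectome(np.ones((3, 3)) - np.eye(3), "abc")
    np.testing.assert_allclose(mx.nodal_clustering(unit_tri), [1, 1, 1])
    star = np.zeros((4, 4))
    star[0, 1:] = star[1:, 0] = 1.0
    np.testing.assert_allclose(
        mx.nodal_clustering(Connectome(star, "abcd")), np.zeros(4)
    )
    got = mx.nodal_clustering(triangle_unequal, normalize_weights=True)
    np.testing.assert_allclose(got, [0.25 ** (1 / 3)] * 3)
    assert mx.global_clustering(unit_tri) == 1.0
    # triangle plus isolated node: average includes the zero
    tri_iso = np.zeros((4, 4))
    tri_iso[:3, :3] = np.ones((3, 3)) - np.eye(3)
    assert mx.global_clustering(Connectome(tri_iso, "abcd")) == 0.75


def test_shortest_paths_examples(triangle_unequal):
    d = mx.shortest_path_matrix(triangle_unequal)
    np.testing.assert_allclose(d, [[0, 1, 2], [1, 0, 2], [2, 2, 0]])
    comp = Connectome(np.ones((5, 5)) - np.eye(5), "abcde")
    d = mx.shortest_path_matrix(comp)
    np.testing.assert_allclose(d + np.eye(5), np.ones((5, 5)))
    two_comp = np.zeros((4, 4))
    two_comp[0, 1] = two_comp[1, 0] = 1.0
    two_comp[2, 3] = two_comp[3, 2] = 1.0
    d = mx.shortest_path_matrix(Connectome(two_comp, "abcd"))
    assert np.isinf(d[0, 2]) and np.isinf(d[1, 3])


def test_cpl_examples():
    unit_tri = Connectome(np.ones((3, 3)) - np.eye(3), "abc")
    assert mx.characteristic_path_length(unit_tri) == 1.0
    path3 = np.zeros((3, 3))
    path3[0, 1] = path3[1, 0] = path3[1, 2] = path3[2, 1] = 1.0
    np.testing.assert_allclose(
        mx.characteristic_path_length(Connectome(path3, "abc")), 4 / 3
    )
    # isolated node: unreachable pairs excluded with a warning
    tri_iso = np.zeros((4, 4))
    tri_iso[:3, :3] = np.ones((3, 3)) - np.eye(3)
    with pytest.warns(UserWarning, match="unreachable"):
        assert mx.characteristic_path_length(Connectome(tri_iso, "abcd")) == 1.0
    with pytest.raises(ValueError, match="no reachable"):
        mx.characteristic_path_length(Connectome(np.zeros((3, 3)), "abc"))


def test_small_worldness_examples():
    unit_tri = Connectome(np.ones((3, 3)) - np.eye(3), "abc")
    assert mx.small_worldness(unit_tri) == 1.0
    star = np.zeros((4, 4))
    star[0, 1:] = star[1:, 0] = 1.0
    assert mx.small_worldness(Connectome(star, "abcd")) == 0.0


def test_regional_efficiency_examples(triangle_unequal):
    comp = Connectome(np.ones((5, 5)) - np.eye(5), "abcde")
    np.testing.assert_allclose(mx.regional_efficiency(comp), np.ones(5))
    tri_iso = np.zeros((4, 4))
    tri_iso[:3, :3] = np.ones((3, 3)) - np.eye(3)
    eff = mx.regional_efficiency(Connectome(tri_iso, "abcd"))
    assert eff[3] == 0.0
    # distances in the unequal triangle: d01=1, d02=d12=2
    np.testing.assert_allclose(
        mx.regional_efficiency(triangle_unequal), [0.75, 0.75, 0.5]
    )


def test_compute_all_consistency(rng):
    conn = random_connectome(10, 0.5, rng)
    nodal, glob = mx.compute_all_metrics(conn)
    np.testing.assert_array_equal(nodal.degree, mx.nodal_degree(conn))
    np.testing.assert_allclose(nodal.strength, mx.nodal_strength(conn))
    np.testing.assert_allclose(nodal.clustering, mx.nodal_clustering(conn))
    np.testing.assert_allclose(nodal.efficiency, mx.regional_efficiency(conn))
    assert glob.edge_density == mx.edge_density(conn)
    assert glob.total_strength == mx.total_strength(conn)
    np.testing.assert_allclose(
        glob.characteristic_path_length, mx.characteristic_path_length(conn)
    )
    np.testing.assert_allclose(
        glob.small_worldness,
        glob.clustering_coefficient / glob.characteristic_path_length,
    )


# ------------------------------------------------------ oracle equivalence

def test_distances_match_floyd_warshall(rng):
    for _ in range(25):
        n = int(rng.integers(2, 7))
        conn = random_connectome(n, rng.uniform(0.2, 0.9), rng)
        np.testing.assert_allclose(
            mx.shortest_path_matrix(conn),
            floyd_warshall_oracle(conn.weights),
            atol=1e-10,
        )


@pytest.mark.parametrize("normalize", [False, True])
def test_clustering_matches_triple_enumeration(rng, normalize):
    for _ in range(25):
        n = int(rng.integers(3, 7))
        conn = random_connectome(n, rng.uniform(0.2, 0.9), rng)
        np.testing.assert_allclose(
            mx.nodal_clustering(conn, normalize),
            onnela_oracle(conn.weights, normalize),
            atol=1e-10,
        )


def test_binary_weights_reduce_to_binary_clustering(rng):
    conn = random_connectome(8, 0.5, rng)
    binary = Connectome((conn.weights > 0).astype(float), conn.node_labels)
    g = nx.from_numpy_array(binary.weights)
    expected = np.array([nx.clustering(g)[i] for i in range(8)])
    np.testing.assert_allclose(mx.nodal_clustering(binary), expected, atol=1e-12)


# ---------------------------------------------------------- property tests

@st.composite
def connectomes(draw):
    n = draw(st.integers(3, 8))
    bits = draw(
        st.lists(st.booleans(), min_size=n * (n - 1) // 2,
                 max_size=n * (n - 1) // 2)
    )
    vals = draw(
        st.lists(
            st.floats(0.1, 50.0, allow_nan=False),
            min_size=n * (n - 1) // 2, max_size=n * (n - 1) // 2,
        )
    )
    w = np.zeros((n, n))
    iu = np.triu_indices(n, 1)
    weights = np.array(vals) * np.array(bits)
    w[iu] = weights
    return Connectome(w + w.T, tuple(f"n{i}" for i in range(n)))


@given(conn=connectomes(), perm_seed=st.integers(0, 10_000))
@settings(max_examples=40, deadline=None, derandomize=True)
def test_permutation_equivariance(conn, perm_seed):
    """Relabelling nodes permutes nodal vectors and fixes global scalars."""
    rng = np.random.default_rng(perm_seed)
    p = rng.permutation(conn.n_nodes)
    permuted = Connectome(
        conn.weights[np.ix_(p, p)], tuple(conn.node_labels[i] for i in p)
    )
    np.testing.assert_allclose(
        mx.nodal_strength(permuted), mx.nodal_strength(conn)[p]
    )
    np.testing.assert_array_equal(
        mx.nodal_degree(permuted), mx.nodal_degree(conn)[p]
    )
    np.testing.assert_allclose(
        mx.nodal_clustering(permuted), mx.nodal_clustering(conn)[p], atol=1e-9
    )
    np.testing.assert_allclose(
        mx.regional_efficiency(permuted), mx.regional_efficiency(conn)[p],
        atol=1e-9,
    )
    assert mx.edge_density(permuted) == mx.edge_density(conn)
    np.testing.assert_allclose(
        mx.total_strength(permuted), mx.total_strength(conn)
    )


@given(conn=connectomes(), c=st.floats(0.1, 20.0))
@settings(max_examples=40, deadline=None, derandomize=True)
def test_weight_rescaling(conn, c):
    """Scaling weights by c scales strengths by c, distances by 1/c, and
    leaves degree, density and normalised clustering unchanged."""
    scaled = Connectome(conn.weights * c, conn.node_labels)
    np.testing.assert_allclose(
        mx.nodal_strength(scaled), c * mx.nodal_strength(conn), rtol=1e-9
    )
    np.testing.assert_array_equal(
        mx.nodal_degree(scaled), mx.nodal_degree(conn)
    )
    assert mx.edge_density(scaled) == mx.edge_density(conn)
    np.testing.assert_allclose(
        mx.shortest_path_matrix(scaled),
        mx.shortest_path_matrix(conn) / c,
        rtol=1e-9,
    )
    np.testing.assert_allclose(
        mx.regional_efficiency(scaled),
        c * mx.regional_efficiency(conn),
        rtol=1e-9,
    )
    np.testing.assert_allclose(
        mx.nodal_clustering(scaled, normalize_weights=True),
        mx.nodal_clustering(conn, normalize_weights=True),
        rtol=1e-9,
    )


# ------------------------------------------------------------ metric tables

def test_metric_tables_shapes(rng):
    conns = [random_connectome(12, 0.5, rng, subject_id=f"s{i}") for i in range(4)]
    nodal, global_df = mx.compute_metric_tables(conns)
    assert set(nodal) == set(mx.NODAL_MEASURES)
    assert nodal["strength"].shape == (4, 12)
    assert global_df.shape == (4, 5)
    long = mx.metrics_long_table(nodal, global_df)
    assert len(long) == 4 * (12 * 4 + 5)
    assert (long.loc[long["scope"] == "global", "node_label"] == "").all()
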