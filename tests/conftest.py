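import numpy as np
import pytest

import annotmix as am


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_connectome(n=20, density=0.3, seed=0, weighted=True, n_annotations=1):
    """Small random weighted undirected connectome with Gaussian annotations."""
    rng = np.random.default_rng(seed)
    coords = rng.uniform(0, 10, size=(n, 3))
    adj = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    present = rng.random(len(iu[0])) < density
    w = rng.uniform(0.5, 2.0, size=len(iu[0])) if weighted else np.ones(len(iu[0]))
    adj[iu[0][present], iu[1][present]] = w[present]
    adj += adj.T
    if not np.any(adj):  # guarantee at least one edge
        adj[0, 1] = adj[1, 0] = 1.0
    annotations = {
        f"x{k}": rng.standard_normal(n) for k in range(n_annotations)
    }
    return am.AnnotatedConnectome(adjacency=adj, coords=coords, annotations=annotations)


@pytest.fixture
def small_conn():
    return random_connectome(n=20, seed=1)


@pytest.fixture(scope="session")
def sphere_geometry():
    spec = am.SyntheticSpec(n_nodes=80, seed=7)
    return am.make_geometry(spec)


@pytest.fixture(scope="session")
def sphere_conn(sphere_geometry):
    spec = am.SyntheticSpec(n_nodes=80, seed=7)
    conn = am.make_network(sphere_geometry, spec)
    x, _ = am.make_annotation(sphere_geometry, spec)
    y, _ = am.make_annotation(
        sphere_geometry, spec, rng=np.random.default_rng(555)
    )
    return conn.with_annotations({"x": x, "y": y})


def edge_list_pearson(conn, name):
    """Independent oracle: weighted Pearson correlation of endpoint lists.

    Enumerates every ordered nonzero entry of the adjacency directly from
    the matrix, never via the package's EdgeTable.
    """
    A = np.asarray(conn.adjacency)
    x = conn.annotations[name]
    ii, jj = np.nonzero(A)
    w = A[ii, jj]
    u, v = x[ii], x[jj]
    sw = w.sum()
    mu, mv = w @ u / sw, w @ v / sw
    cov = w @ ((u - mu) * (v - mv)) / sw
    su = np.sqrt(w @ (u - mu) ** 2 / sw)
    sv = np.sqrt(w @ (v - mv) ** 2 / sw)
    return cov / (su * sv)
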