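import networkx as nx
import numpy as np
import pytest

import annotmix as am
from annotmix import ValidationError

from conftest import edge_list_pearson, random_connectome


def complete_bipartite(n1, n2):
    adj = np.zeros((n1 + n2, n1 + n2))
    adj[:n1, n1:] = 1.0
    adj[n1:, :n1] = 1.0
    return am.AnnotatedConnectome(
        adjacency=adj, coords=np.random.default_rng(0).normal(size=(n1 + n2, 3))
    )


def two_cliques(k):
    n = 2 * k
    adj = np.zeros((n, n))
    adj[:k, :k] = 1.0
    adj[k:, k:] = 1.0
    np.fill_diagonal(adj, 0.0)
    return am.AnnotatedConnectome(
        adjacency=adj, coords=np.random.default_rng(1).normal(size=(n, 3))
    )


class TestAssortativity:
    def test_complete_bipartite_opposed_scores(self):
        conn = complete_bipartite(4, 4)
        conn.annotations["x"] = np.array([1.0] * 4 + [-1.0] * 4)
        assert am.assortativity(conn, "x") == pytest.approx(-1.0, abs=1e-12)

    def test_two_cliques_constant_within(self):
        conn = two_cliques(5)
        conn.annotations["x"] = np.array([2.0] * 5 + [7.0] * 5)
        assert am.assortativity(conn, "x") == pytest.approx(1.0, abs=1e-12)

    def test_matches_edge_list_oracle(self):
        conn = random_connectome(n=30, seed=11)
        r = am.assortativity(conn, "x0")
        assert r == pytest.approx(edge_list_pearson(conn, "x0"), abs=1e-12)

    def test_constant_annotation_errors(self, small_conn):
        conn = small_conn.with_annotations({"c": np.ones(small_conn.n_nodes)})
        with pytest.raises(ValidationError, match="zero weighted variance"):
            am.assortativity(conn, "c")

    def test_empty_graph_errors(self):
        conn = am.AnnotatedConnectome(
            adjacency=np.zeros((4, 4)),
            coords=np.zeros((4, 3)),
            annotations={"x": np.arange(4.0)},
        )
        with pytest.raises(ValidationError):
            am.assortativity(conn, "x")

    @pytest.mark.parametrize("seed", range(20))
    def test_oracle_equivalence_random_graphs(self, seed):
        n = 10 + (seed * 2) % 41
        conn = random_connectome(n=n, seed=seed + 100, density=0.3)
        r = am.assortativity(conn, "x0")
        assert abs(r - edge_list_pearson(conn, "x0")) < 1e-12
        assert -1 - 1e-9 <= r <= 1 + 1e-9

    @pytest.mark.parametrize("a,b", [(2.0, 3.0), (-1.5, 0.0), (0.1, -4.0)])
    def test_affine_invariance(self, small_conn, a, b):
        # both endpoints are standardized with the same moments, so the
        # coefficient is invariant under any affine map with a != 0 (a
        # negation flips both endpoint scores and the products cancel)
        x = small_conn.annotations["x0"]
        conn = small_conn.with_annotations({"ax": a * x + b})
        assert am.assortativity(conn, "ax") == pytest.approx(
            am.assortativity(small_conn, "x0"), abs=1e-10
        )

    @pytest.mark.parametrize("a", [2.0, -1.5])
    def test_heterophilic_affine_equivariance(self, a):
        # with only one endpoint rescaled, the sign does follow the slope
        conn = random_connectome(n=20, seed=55, n_annotations=2)
        scaled = conn.with_annotations({"ay": a * conn.annotations["x1"] + 1.0})
        assert am.heterophilic_assortativity(scaled, "x0", "ay") == pytest.approx(
            np.sign(a) * am.heterophilic_assortativity(conn, "x0", "x1"), abs=1e-10
        )

    @pytest.mark.parametrize("seed", range(20))
    def test_unweighted_matches_networkx(self, seed):
        conn = random_connectome(n=20, seed=seed, weighted=False)
        g = nx.from_numpy_array(conn.adjacency)
        x = conn.annotations["x0"]
        nx.set_node_attributes(g, {i: x[i] for i in range(len(x))}, "x")
        expect = nx.numeric_assortativity_coefficient(g, "x")
        assert am.assortativity(conn, "x0") == pytest.approx(expect, abs=1e-9)

    def test_directed_two_m_is_total_arc_weight(self):
        rng = np.random.default_rng(5)
        adj = rng.uniform(0, 1, (12, 12)) * (rng.random((12, 12)) < 0.4)
        np.fill_diagonal(adj, 0.0)
        conn = am.AnnotatedConnectome(
            adjacency=adj,
            coords=rng.normal(size=(12, 3)),
            annotations={"x": rng.standard_normal(12)},
        )
        assert conn.directed
        r = am.assortativity(conn, "x")
        assert -1 - 1e-9 <= r <= 1 + 1e-9


class TestRankAssortativity:
    def test_monotone_invariance(self, small_conn):
        x = small_conn.annotations["x0"]
        conn = small_conn.with_annotations({"ex": np.exp(x)})
        assert am.rank_assortativity(conn, "ex") == pytest.approx(
            am.rank_assortativity(small_conn, "x0"), abs=1e-12
        )

    def test_two_cliques(self):
        conn = two_cliques(4)
        conn.annotations["x"] = np.array([1.0] * 4 + [9.0] * 4)
        assert am.rank_assortativity(conn, "x") == pytest.approx(1.0, abs=1e-12)

    def test_matches_rank_oracle(self):
        from scipy.stats import rankdata

        conn = random_connectome(n=25, seed=21)
        A = conn.adjacency
        x = conn.annotations["x0"]
        ii, jj = np.nonzero(A)
        w = A[ii, jj]
        ri, rj = rankdata(x[ii]), rankdata(x[jj])
        sw = w.sum()
        mu, mv = w @ ri / sw, w @ rj / sw
        expect = (w @ ((ri - mu) * (rj - mv)) / sw) / np.sqrt(
            (w @ (ri - mu) ** 2 / sw) * (w @ (rj - mv) ** 2 / sw)
        )
        assert am.rank_assortativity(conn, "x0") == pytest.approx(expect, abs=1e-12)


class TestPartialAssortativity:
    def test_self_covariate_degenerate(self, small_conn):
        conn = small_conn.with_annotations({"y": small_conn.annotations["x0"]})
        with pytest.raises(ValidationError, match="degenerate residual variance"):
            am.partial_assortativity(conn, "x0", "y", endpoint_mode="symmetric")

    def test_independent_covariate_close_to_plain(self):
        deltas = []
        for seed in range(20):
            conn = random_connectome(n=200, density=0.1, seed=seed, n_annotations=2)
            plain = am.assortativity(conn, "x0")
            part = am.partial_assortativity(conn, "x0", "x1", "symmetric")
            deltas.append(abs(part - plain))
        assert np.mean(deltas) < 0.05

    def test_five_node_normal_equations_oracle(self):
        # independent oracle: explicit two-stage WLS via normal equations
        adj = np.array(
            [
                [0, 2.0, 0, 1.0, 0],
                [2.0, 0, 1.0, 0, 0.5],
                [0, 1.0, 0, 3.0, 0],
                [1.0, 0, 3.0, 0, 1.0],
                [0, 0.5, 0, 1.0, 0],
            ]
        )
        conn = am.AnnotatedConnectome(
            adjacency=adj,
            coords=np.random.default_rng(3).normal(size=(5, 3)),
            annotations={
                "y": np.array([0.3, -1.2, 0.7, 2.0, -0.5]),
                "x": np.array([1.0, 0.2, -0.8, 0.5, 1.5]),
            },
        )
        ii, jj = np.nonzero(adj)
        w = adj[ii, jj]
        y, x = conn.annotations["y"], conn.annotations["x"]

        def wls_resid(t, c):
            X = np.column_stack([np.ones(len(c)), c])
            beta = np.linalg.solve(X.T @ (w[:, None] * X), X.T @ (w * t))
            return t - X @ beta

        r_i = wls_resid(y[ii], x[ii])
        r_j = wls_resid(y[jj], x[ii])  # literal mode: both on x^(i)
        sw = w.sum()
        mi, mj = w @ r_i / sw, w @ r_j / sw
        expect = (w @ ((r_i - mi) * (r_j - mj)) / sw) / np.sqrt(
            (w @ (r_i - mi) ** 2 / sw) * (w @ (r_j - mj) ** 2 / sw)
        )
        got = am.partial_assortativity(conn, "y", "x", "literal")
        assert got == pytest.approx(expect, abs=1e-12)


class TestHeterophilic:
    def test_diagonal_identity(self, small_conn):
        conn = small_conn.with_annotations({"y": small_conn.annotations["x0"]})
        assert am.heterophilic_assortativity(conn, "x0", "y") == pytest.approx(
            am.assortativity(conn, "x0"), abs=1e-12
        )

    def test_symmetry_undirected(self):
        conn = random_connectome(n=20, seed=31, n_annotations=2)
        assert am.heterophilic_assortativity(conn, "x0", "x1") == pytest.approx(
            am.heterophilic_assortativity(conn, "x1", "x0"), abs=1e-12
        )

    def test_sign_flip(self, small_conn):
        conn = small_conn.with_annotations({"neg": -small_conn.annotations["x0"]})
        assert am.heterophilic_assortativity(conn, "x0", "neg") == pytest.approx(
            -am.assortativity(conn, "x0"), abs=1e-12
        )

    def test_matrix_k1_matches_homophilic(self, sphere_conn, sphere_geometry):
        ens = am.spin_nulls(
            sphere_geometry.parcellation, {"x": sphere_conn.annotations["x"]}, 50, 0
        )
        hm = am.heterophilic_matrix(sphere_conn, ["x"], ens)
        assert hm.empirical_r.shape == (1, 1)
        assert hm.empirical_r[0, 0] == pytest.approx(
            am.assortativity(sphere_conn, "x"), abs=1e-12
        )
        res = am.standardized_mixing(sphere_conn, ["x"], ens)[0]
        assert hm.z[0, 0] == pytest.approx(res.z, abs=1e-9)

    def test_matrix_symmetric_for_undirected(self, sphere_conn, sphere_geometry):
        ann = {k: sphere_conn.annotations[k] for k in ("x", "y")}
        ens = am.spin_nulls(sphere_geometry.parcellation, ann, 60, 1)
        hm = am.heterophilic_matrix(sphere_conn, ["x", "y"], ens)
        np.testing.assert_allclose(hm.empirical_r, hm.empirical_r.T, atol=1e-10)
        np.testing.assert_allclose(hm.z, hm.z.T, atol=1e-9)

    def test_requires_joint_ensemble(self, sphere_conn):
        ens = am.naive_nulls(
            {k: sphere_conn.annotations[k] for k in ("x", "y")}, 20, 0, joint=False
        )
        with pytest.raises(ValidationError, match="joint ensemble"):
            am.heterophilic_matrix(sphere_conn, ["x", "y"], ens)


class TestHomophilicRatio:
    def test_complete_graph_constant(self):
        n = 8
        adj = np.ones((n, n)) - np.eye(n)
        conn = am.AnnotatedConnectome(
            adjacency=adj,
            coords=np.random.default_rng(2).normal(size=(n, 3)),
            annotations={"x": np.random.default_rng(3).standard_normal(n)},
        )
        h = am.homophilic_ratio(conn, "x")
        np.testing.assert_allclose(h, n / (n - 1), atol=1e-12)

    def test_star_center(self):
        n = 6
        adj = np.zeros((n, n))
        adj[0, 1:] = adj[1:, 0] = 1.0
        conn = am.AnnotatedConnectome(
            adjacency=adj,
            coords=np.random.default_rng(4).normal(size=(n, 3)),
            annotations={"x": np.array([5.0] + [1.0] * (n - 1))},
        )
        h = am.homophilic_ratio(conn, "x")
        # center: numerator mean |5-1| = 4; denominator (n-1)*4/n
        assert h[0] == pytest.approx(n / (n - 1), abs=1e-12)

    def test_most_similar_neighbor_below_one(self):
        rng = np.random.default_rng(8)
        n = 50
        x = rng.standard_normal(n)
        adj = np.zeros((n, n))
        # node 0 connects only to its most-similar other node
        target = np.argsort(np.abs(x - x[0]))[1]
        adj[0, target] = adj[target, 0] = 1.0
        # sprinkle other edges not touching node 0
        for _ in range(100):
            i, j = rng.integers(1, n, 2)
            if i != j:
                adj[i, j] = adj[j, i] = 1.0
        conn = am.AnnotatedConnectome(
            adjacency=adj, coords=rng.normal(size=(n, 3)), annotations={"x": x}
        )
        h = am.homophilic_ratio(conn, "x")
        assert h[0] < 1

    def test_isolated_node_undefined(self):
        adj = np.zeros((4, 4))
        adj[0, 1] = adj[1, 0] = 1.0
        conn = am.AnnotatedConnectome(
            adjacency=adj,
            coords=np.zeros((4, 3)),
            annotations={"x": np.arange(4.0)},
        )
        h = am.homophilic_ratio(conn, "x")
        assert np.isnan(h[2]) and np.isnan(h[3])
        assert np.isfinite(h[0])

    def test_direct_formula_oracle(self):
        conn = random_connectome(n=15, seed=77)
        x = conn.annotations["x0"]
        h = am.homophilic_ratio(conn, "x0")
        n = conn.n_nodes
        for i in range(n):
            k = conn.adjacency[i].sum()
            num = sum(
                conn.adjacency[i, j] / k * abs(x[i] - x[j]) for j in range(n)
            )
            den = sum(abs(x[i] - x[j]) for j in range(n)) / n
            assert h[i] == pytest.approx(num / den, abs=1e-12)


class TestMeanHomophilicRatio:
    def test_single_annotation_identity(self, small_conn):
        np.testing.assert_allclose(
            am.mean_homophilic_ratio(small_conn, ["x0"]),
            am.homophilic_ratio(small_conn, "x0"),
        )

    def test_duplicate_annotations_identity(self, small_conn):
        conn = small_conn.with_annotations({"dup": small_conn.annotations["x0"]})
        np.testing.assert_allclose(
            am.mean_homophilic_ratio(conn, ["x0", "dup"]),
            am.homophilic_ratio(conn, "x0"),
        )

    def test_elementwise_mean_oracle(self):
        conn = random_connectome(n=18, seed=5, n_annotations=3)
        names = ["x0", "x1", "x2"]
        stack = np.array([am.homophilic_ratio(conn, nm) for nm in names])
        np.testing.assert_allclose(
            am.mean_homophilic_ratio(conn, names), stack.mean(axis=0)
        )


class TestMeanConnectionDistance:
    def test_single_edge_both_modes(self):
        adj = np.zeros((4, 4))
        adj[0, 1] = adj[1, 0] = 1.0
        adj[2, 3] = adj[3, 2] = 2.0
        coords = np.array([[0, 0, 0], [3, 0, 0], [0, 1, 0], [0, 5, 0]], dtype=float)
        conn = am.AnnotatedConnectome(adjacency=adj, coords=coords)
        two_m = conn.total_weight
        mcd = am.mean_connection_distance(conn, "as_printed")
        assert mcd[0] == pytest.approx(3.0 / two_m)
        per = am.mean_connection_distance(conn, "per_node")
        assert per[0] == pytest.approx(3.0)
        assert per[3] == pytest.approx(4.0)

    def test_equal_lengths_per_node(self):
        n = 5
        adj = np.ones((n, n)) - np.eye(n)
        # place nodes at vertices of a regular simplex: all pairs equidistant
        basis = np.eye(n)[:, :3]
        coords = np.array(
            [
                [1, 0, 0],
                [-1, 0, 0],
                [0, 1, 0],
                [0, -1, 0],
            ],
            dtype=float,
        )
        adj = np.ones((4, 4)) - np.eye(4)
        # square in plane: not all equal; use explicit distances instead
        d = np.ones((4, 4)) * 2.5
        np.fill_diagonal(d, 0.0)
        conn = am.AnnotatedConnectome(adjacency=adj, coords=coords, distances=d)
        per = am.mean_connection_distance(conn, "per_node")
        np.testing.assert_allclose(per, 2.5)

    def test_matches_direct_summation(self):
        conn = random_connectome(n=30, seed=13)
        got = am.mean_connection_distance(conn, "as_printed")
        expect = (conn.distances * conn.adjacency).sum(1) / conn.adjacency.sum()
        np.testing.assert_allclose(got, expect, atol=1e-12)
        per = am.mean_connection_distance(conn, "per_node")
        expect = (conn.distances * conn.adjacency).sum(1) / conn.adjacency.sum(1)
        np.testing.assert_allclose(per, expect, atol=1e-12)


class TestWeightedMoments:
    def test_standardized_moments(self, small_conn):
        x = small_conn.annotations["x0"]
        k = small_conn.strengths_out
        two_m = small_conn.total_weight
        wm = am.weighted_moments(x, k, two_m)
        assert k @ wm.standardized / two_m == pytest.approx(0, abs=1e-10)
        assert k @ wm.standardized**2 / two_m == pytest.approx(1, abs=1e-10)
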