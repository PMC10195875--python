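"""Mixing statistics for annotated networks.

Global annotation assortativity is the connection-weighted Pearson
correlation between the annotation values at the two endpoints of every
edge::

    r_x = sum_ij (a_ij / 2m) x~_i x~_j

where ``x~`` standardizes the annotation with strength-weighted moments
(weights ``k_i / 2m``).  Rank-based and partial variants, heterophilic
mixing between two different annotations, the per-node homophilic ratio
and the mean connection distance live here as well.

Directed graphs use out-strengths for endpoint-i moments and in-strengths
for endpoint-j moments, with 2m the total arc weight.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .connectome import AnnotatedConnectome, ValidationError, edge_table

_VAR_EPS = 1e-300
# residual variances below this fraction of the raw second moment are
# treated as numerically zero (e.g. residuals of y regressed on itself)
_REL_VAR_EPS = 1e-16


@dataclass
class WeightedMoments:
    """Strength-weighted mean, standard deviation and standardized scores."""

    mean: float
    std: float
    standardized: np.ndarray


def weighted_moments(x: np.ndarray, strengths: np.ndarray, total: float) -> WeightedMoments:
    """Standardize ``x`` with weights ``strengths / total``.

    Raises on zero weighted variance (constant annotation).
    """
    x = np.asarray(x, dtype=float)
    mean = float(strengths @ x / total)
    var = float(strengths @ (x - mean) ** 2 / total)
    if var <= _VAR_EPS:
        raise ValidationError("zero weighted variance: annotation is constant")
    std = float(np.sqrt(var))
    return WeightedMoments(mean=mean, std=std, standardized=(x - mean) / std)


def _check_graph(conn: AnnotatedConnectome):
    if conn.total_weight == 0 or not np.any(conn.adjacency):
        raise ValidationError("graph has no edges")


def _endpoint_standardized(conn: AnnotatedConnectome, x: np.ndarray):
    """Standardized scores for endpoint-i and endpoint-j roles."""
    two_m = conn.total_weight
    xi = weighted_moments(x, conn.strengths_out, two_m).standardized
    if conn.directed:
        xj = weighted_moments(x, conn.strengths_in, two_m).standardized
    else:
        xj = xi
    return xi, xj, two_m


def assortativity(conn: AnnotatedConnectome, annotation: str) -> float:
    """Connection-weighted Pearson correlation of endpoint annotations."""
    _check_graph(conn)
    x = conn.annotation(annotation)
    xi, xj, two_m = _endpoint_standardized(conn, x)
    return float(xi @ conn.adjacency @ xj / two_m)


def weighted_pearson(u: np.ndarray, v: np.ndarray, w: np.ndarray) -> float:
    """Pearson correlation of ``u`` and ``v`` under weights ``w``."""
    w = np.asarray(w, dtype=float)
    sw = w.sum()
    mu, mv = w @ u / sw, w @ v / sw
    du, dv = u - mu, v - mv
    cov = w @ (du * dv) / sw
    vu = w @ du**2 / sw
    vv = w @ dv**2 / sw
    if vu <= _VAR_EPS or vv <= _VAR_EPS:
        raise ValidationError("degenerate residual variance in weighted correlation")
    return float(cov / np.sqrt(vu * vv))


def rank_assortativity(conn: AnnotatedConnectome, annotation: str) -> float:
    """Weighted Spearman correlation of endpoint annotations.

    Endpoint vectors are ranked separately (average ranks for ties), then
    correlated with connection weights as in :func:`assortativity`.
    """
    _check_graph(conn)
    et = edge_table(conn)
    xi, xj = et.endpoint_values(annotation)
    ri = rankdata(xi, method="average")
    rj = rankdata(xj, method="average")
    return weighted_pearson(ri, rj, et.weight)


def _wls_residuals(y: np.ndarray, x: np.ndarray, w: np.ndarray) -> np.ndarray:
    sw = w.sum()
    mx, my = w @ x / sw, w @ y / sw
    vx = w @ (x - mx) ** 2 / sw
    if vx <= _VAR_EPS:
        raise ValidationError("covariate has zero weighted variance on edges")
    slope = (w @ ((x - mx) * (y - my)) / sw) / vx
    return y - (my + slope * (x - mx))


def partial_assortativity(
    conn: AnnotatedConnectome,
    target: str,
    covariate: str,
    endpoint_mode: str = "literal",
) -> float:
    """Assortativity of ``target`` after regressing out ``covariate``.

    ``literal`` regresses both endpoint vectors ``y^(i)`` and ``y^(j)`` on
    the covariate's endpoint-i vector ``x^(i)``; ``symmetric`` regresses
    ``y^(j)`` on ``x^(j)`` instead. Residuals are correlated with
    connection weights.
    """
    if endpoint_mode not in ("literal", "symmetric"):
        raise ValueError(f"unknown endpoint_mode {endpoint_mode!r}")
    _check_graph(conn)
    et = edge_table(conn)
    yi, yj = et.endpoint_values(target)
    xci, xcj = et.endpoint_values(covariate)
    w = et.weight
    resid_i = _wls_residuals(yi, xci, w)
    resid_j = _wls_residuals(yj, xci if endpoint_mode == "literal" else xcj, w)
    sw = w.sum()
    for resid, yv in ((resid_i, yi), (resid_j, yj)):
        scale = float(w @ (yv - w @ yv / sw) ** 2 / sw)
        if float(w @ resid**2 / sw) <= _REL_VAR_EPS * max(scale, _VAR_EPS):
            raise ValidationError(
                "degenerate residual variance: covariate explains the target exactly"
            )
    return weighted_pearson(resid_i, resid_j, w)


def heterophilic_assortativity(conn: AnnotatedConnectome, x: str, y: str) -> float:
    """Mixing between two annotations: ``r_xy = sum_ij (a_ij/2m) x~_i y~_j``."""
    _check_graph(conn)
    xv = conn.annotation(x)
    yv = conn.annotation(y)
    two_m = conn.total_weight
    xi = weighted_moments(xv, conn.strengths_out, two_m).standardized
    yj = weighted_moments(
        yv, conn.strengths_in if conn.directed else conn.strengths_out, two_m
    ).standardized
    return float(xi @ conn.adjacency @ yj / two_m)


@dataclass
class HeterophilicMatrix:
    """All-pairs mixing with null-standardized inference."""

    annotation_names: list
    empirical_r: np.ndarray
    z: np.ndarray
    p: np.ndarray
    q: np.ndarray

    def to_frame(self):
        import pandas as pd

        rows = []
        K = len(self.annotation_names)
        for a in range(K):
            for b in range(K):
                rows.append(
                    {
                        "annotation_x": self.annotation_names[a],
                        "annotation_y": self.annotation_names[b],
                        "r": self.empirical_r[a, b],
                        "z": self.z[a, b],
                        "p": self.p[a, b],
                        "q": self.q[a, b],
                    }
                )
        return pd.DataFrame(rows)


def _heterophilic_all_pairs(conn: AnnotatedConnectome, vectors: np.ndarray) -> np.ndarray:
    """K x K matrix of r_xy for rows of ``vectors`` (K x n)."""
    two_m = conn.total_weight
    Xi = np.empty_like(vectors)
    Yj = np.empty_like(vectors)
    for k, v in enumerate(vectors):
        Xi[k] = weighted_moments(v, conn.strengths_out, two_m).standardized
        Yj[k] = weighted_moments(
            v, conn.strengths_in if conn.directed else conn.strengths_out, two_m
        ).standardized
    return Xi @ conn.adjacency @ Yj.T / two_m


def heterophilic_matrix(conn: AnnotatedConnectome, annotations, ensemble) -> HeterophilicMatrix:
    """All-pairs heterophilic mixing standardized against a joint null ensemble.

    The ensemble must have been generated jointly (identical spatial
    transform applied to every annotation within a draw) so that inter-map
    correlations are preserved under the null.
    """
    from .inference import by_fdr, perm_pvalue, z_score

    names = list(annotations)
    if not ensemble.joint:
        raise ValidationError("joint ensemble required for heterophilic inference")
    missing = [nm for nm in names if nm not in ensemble.draws]
    if missing:
        raise KeyError(f"ensemble lacks annotations {missing}")
    vectors = np.array([conn.annotation(nm) for nm in names])
    emp = _heterophilic_all_pairs(conn, vectors)
    K = len(names)
    n_nulls = ensemble.n_nulls
    null_r = np.empty((n_nulls, K, K))
    for t in range(n_nulls):
        surro = np.array([ensemble.draws[nm][t] for nm in names])
        null_r[t] = _heterophilic_all_pairs(conn, surro)
    z = np.empty((K, K))
    p = np.empty((K, K))
    for a in range(K):
        for b in range(K):
            z[a, b] = z_score(emp[a, b], null_r[:, a, b])
            p[a, b] = perm_pvalue(emp[a, b], null_r[:, a, b])
    # BY correction over unique tests only
    if conn.directed:
        ai, bi = np.meshgrid(range(K), range(K), indexing="ij")
        ai, bi = ai.ravel(), bi.ravel()
    else:
        ai, bi = np.triu_indices(K)
    q = np.full((K, K), np.nan)
    q_flat = by_fdr(p[ai, bi])
    q[ai, bi] = q_flat
    if not conn.directed:
        q[bi, ai] = q_flat
    return HeterophilicMatrix(
        annotation_names=names, empirical_r=emp, z=z, p=p, q=q
    )


def homophilic_ratio(conn: AnnotatedConnectome, annotation: str) -> np.ndarray:
    """Per-node ratio of neighborhood to global annotation dissimilarity.

    h_x(i) = [sum_j (a_ij/k_i) |x_i - x_j|] / [(1/n) sum_j |x_i - x_j|]

    The denominator averages over all n nodes including the zero ``j = i``
    term. Values below 1 mark assortative neighborhoods. Isolated nodes and
    nodes whose value equals every other value are undefined (``NaN``).
    """
    x = conn.annotation(annotation)
    n = conn.n_nodes
    diff = np.abs(x[:, None] - x[None, :])
    k = conn.strengths_out
    with np.errstate(divide="ignore", invalid="ignore"):
        num = (conn.adjacency * diff).sum(axis=1) / k
        den = diff.sum(axis=1) / n
        h = num / den
    h[(k == 0) | (den == 0)] = np.nan
    return h


def mean_homophilic_ratio(conn: AnnotatedConnectome, annotations) -> np.ndarray:
    """Unweighted per-node mean of homophilic ratios across annotations.

    Undefined per-annotation values are excluded pairwise; a node undefined
    for every annotation stays ``NaN``.
    """
    names = list(annotations)
    if not names:
        raise ValueError("need at least one annotation")
    stack = np.array([homophilic_ratio(conn, nm) for nm in names])
    with np.errstate(invalid="ignore"):
        return np.nanmean(stack, axis=0)


def mean_connection_distance(
    conn: AnnotatedConnectome, normalization: str = "as_printed"
) -> np.ndarray:
    """Weighted mean length of a node's connections.

    ``as_printed``: MCD(i) = (1/2m) sum_j d_ij a_ij (global normalization).
    ``per_node``:  sum_j d_ij a_ij / k_i — the average distance to connected
    neighbors weighted by connection weight. Isolated nodes are ``NaN`` in
    per-node mode.
    """
    if normalization not in ("as_printed", "per_node"):
        raise ValueError(f"unknown normalization {normalization!r}")
    _check_graph(conn)
    wsum = (conn.distances * conn.adjacency).sum(axis=1)
    if normalization == "as_printed":
        return wsum / conn.total_weight
    k = conn.strengths_out
    with np.errstate(divide="ignore", invalid="ignore"):
        out = wsum / k
    out[k == 0] = np.nan
    return out
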