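"""Synthetic spatially embedded annotated networks.

Generates everything the statistics need with no external data: mirrored
two-hemisphere spherical (or cubic) geometries, distance-decay weighted
networks, spatially autocorrelated annotation fields of controllable
smoothness, planted (dis)assortative wiring via degree-preserving edge
swaps, and term-map sets with planted category correlations.

Planted effects are purely topological (edges are rewired, annotation
values never change), so the spatial autocorrelation of the maps — and
therefore the meaning of spatial-null calibration — is untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist, squareform

from .connectome import AnnotatedConnectome, ValidationError
from .mixing import weighted_moments
from .nulls import SphereParcellation, inverse_distance_weights, moran_basis, morans_i


@dataclass
class SyntheticSpec:
    n_nodes: int = 200
    geometry: str = "sphere_two_hemispheres"  # or "cube"
    decay_length: float = 0.5  # in units of the mean inter-node distance
    target_density: float = 0.1
    autocorr_strength: float = 2.0
    planted_effect: str = "none"  # {none, assortative, disassortative, hetero_pair}
    effect_size: float = 0.1
    seed: int = 0


@dataclass
class Geometry:
    coords: np.ndarray
    distances: np.ndarray
    hemisphere: np.ndarray
    parcellation: SphereParcellation = None
    _basis: tuple = field(default=None, repr=False)

    def moran_eigenbasis(self):
        """Cached Moran eigenbasis of W = 1/d over all nodes."""
        if self._basis is None:
            W = inverse_distance_weights(self.distances)
            self._basis = moran_basis(W)
        return self._basis


SPHERE_RADIUS = 50.0
_MIN_SAGITTAL_GAP = 0.05  # keeps mirrored pairs from coinciding on the plane


def make_geometry(spec: SyntheticSpec) -> Geometry:
    """Place nodes in space; two-hemisphere mode mirrors L onto R exactly."""
    if spec.n_nodes < 6:
        raise ValidationError("need at least 6 nodes")
    rng = np.random.default_rng(spec.seed)
    if spec.geometry == "sphere_two_hemispheres":
        if spec.n_nodes % 2:
            raise ValidationError("two-hemisphere mode needs an even node count")
        nh = spec.n_nodes // 2
        pts = rng.standard_normal((nh, 3))
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
        pts[:, 0] = -np.maximum(np.abs(pts[:, 0]), _MIN_SAGITTAL_GAP)
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
        left = pts
        right = pts.copy()
        right[:, 0] *= -1
        unit = np.vstack([left, right])
        coords = unit * SPHERE_RADIUS
        hemisphere = np.array(["L"] * nh + ["R"] * nh, dtype=object)
        parc = SphereParcellation(
            centroids_L=left,
            centroids_R=right,
            nodes_L=np.arange(nh),
            nodes_R=np.arange(nh, 2 * nh),
        )
    elif spec.geometry == "cube":
        coords = rng.uniform(0, 100, size=(spec.n_nodes, 3))
        hemisphere = np.array(["NA"] * spec.n_nodes, dtype=object)
        parc = None
    else:
        raise ValueError(f"unknown geometry {spec.geometry!r}")
    return Geometry(
        coords=coords,
        distances=squareform(pdist(coords)),
        hemisphere=hemisphere,
        parcellation=parc,
    )


def make_network(geometry: Geometry, spec: SyntheticSpec) -> AnnotatedConnectome:
    """Undirected weighted graph with edge probability ~ exp(-d / lambda).

    ``decay_length`` is expressed as a fraction of the mean inter-node
    distance. The proportionality constant is tuned (capping probabilities
    at 1) to hit ``target_density``; weights decay mildly with distance
    with lognormal jitter. Connectivity is enforced by bridging components
    along their shortest spatial gap.
    """
    if not 0 < spec.target_density < 1:
        raise ValidationError("target_density must be in (0, 1)")
    rng = np.random.default_rng(spec.seed + 1)
    d = geometry.distances
    n = len(d)
    iu = np.triu_indices(n, k=1)
    lam = spec.decay_length * d[iu].mean()
    kernel = np.exp(-d[iu] / lam)
    # bisection on the proportionality constant with capped probabilities
    lo, hi = 0.0, 1.0
    while np.minimum(hi * kernel, 1.0).mean() < spec.target_density:
        hi *= 2
        if hi > 1e12:
            raise ValidationError(
                f"target density {spec.target_density} unreachable; "
                f"feasible range (0, {np.minimum(1e12 * kernel, 1).mean():.3f})"
            )
    for _ in range(100):
        mid = (lo + hi) / 2
        if np.minimum(mid * kernel, 1.0).mean() < spec.target_density:
            lo = mid
        else:
            hi = mid
    probs = np.minimum(hi * kernel, 1.0)
    present = rng.random(len(probs)) < probs
    weights = np.exp(-d[iu] / (2 * lam)) * rng.lognormal(0.0, 0.2, size=len(probs))
    weights /= weights.mean()
    adjacency = np.zeros((n, n))
    adjacency[iu[0][present], iu[1][present]] = weights[present]
    adjacency += adjacency.T
    # bridge disconnected components along the shortest spatial gaps
    n_comp, labels = connected_components(adjacency > 0, directed=False)
    while n_comp > 1:
        best = None
        for c in range(1, n_comp):
            a = np.nonzero(labels == 0)[0]
            b = np.nonzero(labels == c)[0]
            sub = d[np.ix_(a, b)]
            k = np.unravel_index(np.argmin(sub), sub.shape)
            cand = (sub[k], a[k[0]], b[k[1]])
            if best is None or cand[0] < best[0]:
                best = cand
        _, i, j = best
        w = np.median(weights[present]) if present.any() else 1.0
        adjacency[i, j] = adjacency[j, i] = w
        n_comp, labels = connected_components(adjacency > 0, directed=False)
    return AnnotatedConnectome(
        adjacency=adjacency,
        coords=geometry.coords,
        distances=geometry.distances,
        hemisphere=geometry.hemisphere,
        directed=False,
    )


def make_annotation(
    geometry: Geometry,
    spec: SyntheticSpec,
    name: str = "x",
    *,
    rng: np.random.Generator = None,
    homotopic: bool = False,
):
    """Spatially autocorrelated field with controllable smoothness.

    Mixes a smooth field built from the leading Moran eigenvectors of
    ``W = 1/d`` (coefficients scaled by the positive eigenvalues) with
    white noise: ``x = s * smooth + noise`` where ``s`` is
    ``autocorr_strength``; ``s = 0`` yields i.i.d. noise. Returns the
    z-scored vector and its achieved Moran's I. ``homotopic`` mirrors the
    left-hemisphere values onto the right before adding noise (mirrored
    geometries only).
    """
    if spec.autocorr_strength < 0:
        raise ValidationError("autocorr_strength must be >= 0")
    if rng is None:
        rng = np.random.default_rng(spec.seed + 2)
    n = len(geometry.coords)
    vals, V = geometry.moran_eigenbasis()
    # few smoothest modes, eigenvalue-squared weighting: under the dense
    # W = 1/d weights Moran's I is bounded near the leading eigenvalue
    # (~0.31 at n=200), so the calibrated ceiling of this generator is
    # I ~ 0.2-0.25 at large autocorr_strength
    k = max(4, n // 40)
    lam = np.clip(vals[:k], 0, None) ** 2
    smooth = V[:, :k] @ (rng.standard_normal(k) * lam)
    sd = smooth.std()
    if sd > 0:
        smooth = smooth / sd
    if homotopic:
        left = geometry.hemisphere == "L"
        right = geometry.hemisphere == "R"
        if left.sum() != right.sum():
            raise ValidationError("homotopic annotation needs mirrored hemispheres")
        smooth[right] = smooth[left]
    x = spec.autocorr_strength * smooth + rng.standard_normal(n)
    x = (x - x.mean()) / x.std()
    W = inverse_distance_weights(geometry.distances)
    return x, morans_i(W, x)


def _edge_set(adjacency: np.ndarray):
    iu, ju = np.nonzero(np.triu(adjacency, k=1))
    return list(zip(iu.tolist(), ju.tolist()))


def _rebuild(conn: AnnotatedConnectome, edges: dict) -> AnnotatedConnectome:
    out = conn.copy()
    out.adjacency = np.zeros_like(conn.adjacency)
    for (i, j), w in edges.items():
        out.adjacency[i, j] = out.adjacency[j, i] = w
    return out


def _swap_rewire(
    conn: AnnotatedConnectome,
    annotation: str,
    seed: int,
    *,
    sign: float,
    effect_size: float,
    edge_filter=None,
    max_attempts: int = None,
) -> AnnotatedConnectome:
    """Degree-preserving double-edge swaps moving endpoint similarity.

    A swap of edges (a, b), (c, d) into (a, d), (c, b) carries the edge
    weights along and is accepted when it moves the weighted sum of
    standardized endpoint products in the requested direction. Stops once
    plain assortativity has shifted by ``effect_size`` (sign-matched).
    """
    from . import mixing

    if conn.directed:
        raise ValidationError("rewiring requires an undirected graph")
    if effect_size == 0:
        return conn.copy()
    x = conn.annotation(annotation)
    xt = weighted_moments(x, conn.strengths_out, conn.total_weight).standardized
    edges = {
        (i, j): conn.adjacency[i, j] for i, j in _edge_set(conn.adjacency)
    }
    keys = list(edges)
    if edge_filter is not None:
        eligible = [k for k in keys if edge_filter(k)]
    else:
        eligible = keys
    if len(eligible) < 2:
        raise ValidationError("not enough eligible edges to rewire")
    rng = np.random.default_rng(seed)
    r0 = mixing.assortativity(conn, annotation)
    if max_attempts is None:
        max_attempts = 200 * len(keys)
    check_every = max(50, len(keys) // 4)
    accepted = 0
    for attempt in range(max_attempts):
        e1, e2 = rng.choice(len(eligible), size=2, replace=False)
        a, b = eligible[e1]
        c, d = eligible[e2]
        if rng.random() < 0.5:
            b, a = a, b
        if len({a, b, c, d}) < 4:
            continue
        na, nd = (min(a, d), max(a, d))
        nc, nb = (min(c, b), max(c, b))
        if (na, nd) in edges or (nc, nb) in edges:
            continue
        if edge_filter is not None and not (
            edge_filter((na, nd)) and edge_filter((nc, nb))
        ):
            continue
        w1 = edges[eligible[e1]]
        w2 = edges[eligible[e2]]
        delta = (
            w1 * (xt[a] * xt[d] - xt[a] * xt[b])
            + w2 * (xt[c] * xt[b] - xt[c] * xt[d])
        )
        if sign * delta <= 0:
            continue
        old1, old2 = eligible[e1], eligible[e2]
        del edges[old1], edges[old2]
        edges[(na, nd)] = w1
        edges[(nc, nb)] = w2
        eligible[e1] = (na, nd)
        eligible[e2] = (nc, nb)
        accepted += 1
        if accepted % check_every == 0:
            current = _rebuild(conn, edges)
            shift = sign * (mixing.assortativity(current, annotation) - r0)
            if shift >= effect_size:
                return current
    current = _rebuild(conn, edges)
    shift = sign * (mixing.assortativity(current, annotation) - r0)
    if shift >= effect_size:
        return current
    raise ValidationError(
        f"requested shift {effect_size} unattainable within swap budget; "
        f"achieved {shift:.4f}"
    )


def plant_assortativity(
    conn: AnnotatedConnectome,
    annotation: str,
    direction: str = "assortative",
    effect_size: float = 0.1,
    seed: int = 0,
) -> AnnotatedConnectome:
    """Rewire edges (degrees preserved) to shift assortativity by ``effect_size``.

    Node positions and annotation values are untouched, so the planted
    signal is purely topological.
    """
    if direction not in ("assortative", "disassortative"):
        raise ValueError(f"unknown direction {direction!r}")
    sign = 1.0 if direction == "assortative" else -1.0
    return _swap_rewire(
        conn, annotation, seed, sign=sign, effect_size=effect_size
    )


def plant_long_range_disassortativity(
    conn: AnnotatedConnectome,
    annotation: str,
    effect_size: float = 0.1,
    seed: int = 0,
) -> AnnotatedConnectome:
    """Make only above-median-distance edges join dissimilar nodes.

    Swaps are restricted so that both removed and created edges lie above
    the median edge distance; short-range wiring is untouched.
    """
    if effect_size == 0:
        return conn.copy()
    keys = _edge_set(conn.adjacency)
    dists = np.array([conn.distances[i, j] for i, j in keys])
    median_d = np.median(dists)

    def long_range(key):
        return conn.distances[key[0], key[1]] > median_d

    return _swap_rewire(
        conn,
        annotation,
        seed,
        sign=-1.0,
        effect_size=effect_size,
        edge_filter=long_range,
    )


def plant_short_range_assortativity(
    conn: AnnotatedConnectome,
    annotation: str,
    effect_size: float = 0.1,
    seed: int = 0,
) -> AnnotatedConnectome:
    """Make only at-or-below-median-distance edges join similar nodes.

    Mirror of :func:`plant_long_range_disassortativity`; combining the two
    yields the short-range-assortative / long-range-disassortative wiring
    whose distance-threshold z-profile decreases with the percentile of
    short connections removed.
    """
    if effect_size == 0:
        return conn.copy()
    keys = _edge_set(conn.adjacency)
    dists = np.array([conn.distances[i, j] for i, j in keys])
    median_d = np.median(dists)

    def short_range(key):
        return conn.distances[key[0], key[1]] <= median_d

    return _swap_rewire(
        conn,
        annotation,
        seed,
        sign=1.0,
        effect_size=effect_size,
        edge_filter=short_range,
    )


def make_term_maps(
    geometry: Geometry,
    n_terms: int,
    n_categories: int,
    planted_category: int = None,
    planted_r: float = 0.0,
    target_map=None,
    seed: int = 0,
    autocorr_strength: float = 2.0,
):
    """Smooth random term maps with category labels, optionally planted.

    Terms in ``planted_category`` are mixed with the z-scored target map to
    an expected correlation of ``planted_r``; labels are balanced
    round-robin across categories.
    """
    if n_terms < n_categories:
        raise ValidationError("need at least one term per category")
    if not -1 < planted_r < 1:
        raise ValidationError("planted_r must lie in (-1, 1)")
    if planted_r != 0 and (planted_category is None or target_map is None):
        raise ValueError("planted_r requires planted_category and target_map")
    rng = np.random.default_rng(seed)
    n = len(geometry.coords)
    spec = SyntheticSpec(n_nodes=n, autocorr_strength=autocorr_strength)
    labels = np.array([t % n_categories for t in range(n_terms)])
    maps = np.empty((n, n_terms))
    tz = None
    if target_map is not None:
        tz = (np.asarray(target_map, dtype=float) - np.mean(target_map)) / np.std(
            target_map
        )
    for t in range(n_terms):
        base, _ = make_annotation(geometry, spec, rng=rng)
        if planted_category is not None and labels[t] == planted_category and planted_r:
            base = planted_r * tz + np.sqrt(1 - planted_r**2) * base
        maps[:, t] = base
    return maps, labels
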