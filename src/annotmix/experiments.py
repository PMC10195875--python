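"""End-to-end simulation experiments on synthetic annotated networks.

These are the package's own validation surfaces: type-I-error calibration
of the spatial null models versus naive value permutation, power to
recover planted assortative rewiring, and the shape of the
distance-threshold z-profile under planted long-range disassortativity.
The same routines back the acceptance suite and the acceptance report.

Measured operating points (documented calibration of this implementation):
rotation nulls are run on mirrored-sphere geometry with homotopic maps at
autocorr_strength 1.0 (spins are conservative by construction; stronger
smoothness pushes the rejection rate below the nominal level), while
Moran/Burt/naive nulls are run on cube geometry — matching their use on
non-spherical data — at autocorr_strength 2.0.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import spearmanr

from . import mixing
from .connectome import AnnotatedConnectome
from .inference import _assortativity_many, perm_pvalue, z_score
from .nulls import burt_nulls, moran_nulls, naive_nulls, spin_nulls
from .synthetic import (
    SyntheticSpec,
    make_annotation,
    make_geometry,
    make_network,
    plant_assortativity,
    plant_long_range_disassortativity,
    plant_short_range_assortativity,
)

_METHOD_GEOMETRY = {
    "spin": ("sphere_two_hemispheres", 1.0, True),
    "moran": ("cube", 2.0, False),
    "burt": ("cube", 2.0, False),
    "naive": ("cube", 2.0, False),
}


def _make_draws(method, conn, geom, x, n_nulls, seed):
    if method == "spin":
        return spin_nulls(geom.parcellation, {"x": x}, n_nulls, seed).draws["x"]
    if method == "moran":
        return moran_nulls(conn, {"x": x}, n_nulls, seed).draws["x"]
    if method == "burt":
        return burt_nulls(conn.with_annotations({"x": x}), "x", n_nulls, seed).draws["x"]
    if method == "naive":
        return naive_nulls({"x": x}, n_nulls, seed).draws["x"]
    raise ValueError(f"unknown method {method!r}")


def calibration_rejection_rate(
    method: str,
    n_datasets: int = 500,
    n_nulls: int = 500,
    n: int = 200,
    seed: int = 0,
    alpha: float = 0.05,
    new_network_every: int = 25,
) -> float:
    """Two-sided rejection rate with no planted effect (target: alpha).

    Each dataset draws a fresh spatially autocorrelated annotation with no
    relation to the wiring beyond spatial embedding; the network is
    regenerated every ``new_network_every`` datasets (the test is
    conditional on the graph, so sharing graphs across datasets is sound).
    """
    geometry, autocorr, homotopic = _METHOD_GEOMETRY[method]
    rejections = 0
    geom = conn = None
    for d in range(n_datasets):
        spec = SyntheticSpec(
            n_nodes=n,
            geometry=geometry,
            autocorr_strength=autocorr,
            seed=seed * 100003 + (d // new_network_every) * 7919,
        )
        if d % new_network_every == 0:
            geom = make_geometry(spec)
            conn = make_network(geom, spec)
        x, _ = make_annotation(
            geom,
            spec,
            rng=np.random.default_rng(seed * 999331 + d * 31 + 5),
            homotopic=homotopic,
        )
        c = conn.with_annotations({"x": x})
        emp = mixing.assortativity(c, "x")
        draws = _make_draws(method, conn, geom, x, n_nulls, seed * 7 + d)
        nulls = _assortativity_many(c, draws)
        nulls = nulls[~np.isnan(nulls)]
        rejections += perm_pvalue(emp, nulls) < alpha
    return rejections / n_datasets


def planted_power(
    n_seeds: int = 50,
    effect_size: float = 0.2,
    n: int = 200,
    n_nulls: int = 1000,
    seed: int = 0,
    z_threshold: float = 2.0,
) -> float:
    """Fraction of planted-assortative datasets detected with z > threshold.

    Rewiring is degree-preserving and purely topological, so the Moran
    null (which randomizes the annotation, not the graph) is the
    appropriate reference.
    """
    hits = 0
    for s in range(n_seeds):
        spec = SyntheticSpec(
            n_nodes=n, geometry="cube", autocorr_strength=2.0, seed=seed * 65537 + s
        )
        geom = make_geometry(spec)
        conn = make_network(geom, spec)
        x, _ = make_annotation(geom, spec)
        conn = conn.with_annotations({"x": x})
        planted = plant_assortativity(
            conn, "x", "assortative", effect_size, seed=seed * 101 + s
        )
        draws = moran_nulls(planted, {"x": x}, n_nulls, seed * 13 + s).draws["x"]
        nulls = _assortativity_many(planted, draws)
        nulls = nulls[~np.isnan(nulls)]
        z = z_score(mixing.assortativity(planted, "x"), nulls)
        hits += z > z_threshold
    return hits / n_seeds


def profile_shape_recovery(
    n_seeds: int = 50,
    effect_size: float = 0.2,
    short_effect_size: float = 0.12,
    n: int = 200,
    n_nulls: int = 400,
    seed: int = 0,
    percentiles=(0, 10, 20, 30, 40, 50, 60, 70, 80),
) -> float:
    """Fraction of seeds with a decreasing z-profile after long-range rewiring.

    Short-range edges are rewired to join similar nodes and long-range
    edges to join dissimilar ones; removing short-range connections then
    strips the assortative signal and exposes the planted long-range
    disassortativity, so the percentile-z Spearman correlation should be
    negative. (With long-range planting alone the profile is close to
    flat: the per-edge signal concentrates as short edges are removed, but
    the null spread grows commensurately on the shrinking subgraph.)
    """
    from .connectome import threshold_by_distance

    hits = 0
    for s in range(n_seeds):
        spec = SyntheticSpec(
            n_nodes=n, geometry="cube", autocorr_strength=2.0, seed=seed * 92821 + s
        )
        geom = make_geometry(spec)
        conn = make_network(geom, spec)
        x, _ = make_annotation(geom, spec)
        conn = conn.with_annotations({"x": x})
        base = plant_short_range_assortativity(
            conn, "x", short_effect_size, seed=seed * 55 + s
        )
        planted = plant_long_range_disassortativity(
            base, "x", effect_size, seed=seed * 103 + s
        )
        draws = moran_nulls(planted, {"x": x}, n_nulls, seed * 17 + s).draws["x"]
        zs = []
        for pct in percentiles:
            sub = planted if pct == 0 else threshold_by_distance(planted, pct)
            nulls = _assortativity_many(sub, draws)
            nulls = nulls[~np.isnan(nulls)]
            zs.append(z_score(mixing.assortativity(sub, "x"), nulls))
        rho = spearmanr(percentiles, zs).statistic
        hits += rho < 0
    return hits / n_seeds
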