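"""Permutation inference against null annotation ensembles.

Empirical statistics are standardized against the null distribution
(z-score), assigned two-sided permutation p-values, and corrected for
false discovery rate with the Benjamini-Yekutieli step-up procedure
(valid under arbitrary dependence). Higher-level procedures: the
distance-threshold z-profile and term-category decoding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import mixing
from .connectome import AnnotatedConnectome, ValidationError, threshold_by_distance
from .mixing import weighted_moments
from .nulls import NullEnsemble

MAX_DROP_FRACTION = 0.01


@dataclass
class MixingResult:
    """One (statistic, annotation) test: empirical value + null inference."""

    statistic_name: str
    annotation: tuple
    empirical: float
    null_values: np.ndarray
    z: float
    p: float
    q: float = np.nan
    n_dropped: int = 0


@dataclass
class ZProfile:
    """z-assortativity as a function of the percentile of short edges removed."""

    percentiles: np.ndarray
    z_values: np.ndarray
    p_values: np.ndarray
    empirical: np.ndarray


def z_score(empirical: float, null_values) -> float:
    """Standardize against the null distribution (sample standard deviation)."""
    nulls = np.asarray(null_values, dtype=float)
    if len(nulls) < 2:
        raise ValidationError("need at least 2 null values for a z-score")
    sd = nulls.std(ddof=1)
    scale = max(float(np.abs(nulls).max()), 1.0)
    if sd <= 1e-12 * scale:
        raise ValidationError("zero null spread")
    return float((empirical - nulls.mean()) / sd)


def perm_pvalue(
    empirical: float, null_values, sided: str = "two", convention: str = "mean_deviation"
) -> float:
    """Two-sided permutation p-value with add-one correction.

    ``mean_deviation`` (default): extremeness is the absolute deviation
    from the null mean, ``p = (1 + #{|null_t - mean| >= |emp - mean|}) / (T + 1)``.
    ``tail_doubling`` doubles the smaller one-sided tail instead.
    """
    if sided != "two":
        raise ValueError("only two-sided tests are supported")
    nulls = np.asarray(null_values, dtype=float)
    T = len(nulls)
    if T == 0:
        raise ValidationError("empty null distribution")
    if convention == "mean_deviation":
        mu = nulls.mean()
        count = int(np.sum(np.abs(nulls - mu) >= np.abs(empirical - mu)))
        return (1 + count) / (T + 1)
    if convention == "tail_doubling":
        hi = (1 + int(np.sum(nulls >= empirical))) / (T + 1)
        lo = (1 + int(np.sum(nulls <= empirical))) / (T + 1)
        return float(min(1.0, 2 * min(hi, lo)))
    raise ValueError(f"unknown convention {convention!r}")


def by_fdr(p_values) -> np.ndarray:
    """Benjamini-Yekutieli step-up adjusted q-values.

    q_(i) = min_{j >= i} [ K * c(K) * p_(j) / j ] clipped at 1, with
    c(K) = sum_{k=1..K} 1/k.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValidationError("p-values must lie in (0, 1]")
    K = p.size
    c = np.sum(1.0 / np.arange(1, K + 1))
    order = np.argsort(p, kind="stable")
    ranked = p[order] * K * c / np.arange(1, K + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.clip(q_sorted, 0, 1)
    q = np.empty(K)
    q[order] = q_sorted
    return q


def _assortativity_many(conn: AnnotatedConnectome, X: np.ndarray) -> np.ndarray:
    """Assortativity of every row of X (T x n) on a fixed graph, vectorized."""
    two_m = conn.total_weight
    ko = conn.strengths_out
    mo = X @ ko / two_m
    Xc = X - mo[:, None]
    vo = (Xc**2) @ ko / two_m
    with np.errstate(divide="ignore", invalid="ignore"):
        Xi = Xc / np.sqrt(vo)[:, None]
    if conn.directed:
        ki = conn.strengths_in
        mi = X @ ki / two_m
        Xcj = X - mi[:, None]
        vi = (Xcj**2) @ ki / two_m
        with np.errstate(divide="ignore", invalid="ignore"):
            Xj = Xcj / np.sqrt(vi)[:, None]
    else:
        Xj = Xi
        vi = vo
    r = np.einsum("tn,nm,tm->t", Xi, conn.adjacency, Xj) / two_m
    r[(vo <= 0) | (vi <= 0)] = np.nan
    return r


def _null_statistic(conn, statistic, names, surrogate_rows):
    """Evaluate one statistic over an ensemble; NaN marks undefined draws."""
    if statistic == "assortativity":
        return _assortativity_many(conn, surrogate_rows[names[0]])
    T = next(iter(surrogate_rows.values())).shape[0]
    out = np.empty(T)
    for t in range(T):
        try:
            if statistic == "rank":
                out[t] = mixing.rank_assortativity(
                    conn.with_annotations({names[0]: surrogate_rows[names[0]][t]}),
                    names[0],
                )
            elif statistic == "heterophilic":
                out[t] = mixing.heterophilic_assortativity(
                    conn.with_annotations(
                        {nm: surrogate_rows[nm][t] for nm in names}
                    ),
                    names[0],
                    names[1],
                )
            else:
                raise ValueError(f"unknown statistic {statistic!r}")
        except ValidationError:
            out[t] = np.nan
    return out


def standardized_mixing(
    conn: AnnotatedConnectome,
    annotations,
    ensemble: NullEnsemble,
    statistic: str = "assortativity",
) -> list:
    """Standardize a mixing statistic against a null ensemble.

    ``annotations`` is a list of names (or of name pairs for the
    heterophilic statistic). The graph is fixed; only the annotation is
    replaced by each surrogate. Null draws on which the statistic is
    undefined are dropped and counted; more than 1% drops is an error.
    q-values are BY-corrected across the tested family.
    """
    items = [(a,) if isinstance(a, str) else tuple(a) for a in annotations]
    if statistic == "heterophilic" and any(len(it) != 2 for it in items):
        raise ValueError("heterophilic statistic requires (x, y) name pairs")
    if statistic == "heterophilic" and not ensemble.joint:
        raise ValidationError("joint ensemble required for heterophilic inference")
    results = []
    for item in items:
        for nm in item:
            if nm not in ensemble.draws:
                raise KeyError(f"ensemble lacks surrogates for annotation {nm!r}")
        if statistic == "assortativity":
            emp = mixing.assortativity(conn, item[0])
        elif statistic == "rank":
            emp = mixing.rank_assortativity(conn, item[0])
        elif statistic == "heterophilic":
            emp = mixing.heterophilic_assortativity(conn, item[0], item[1])
        else:
            raise ValueError(f"unknown statistic {statistic!r}")
        nulls = _null_statistic(
            conn, statistic, list(item), {nm: ensemble.draws[nm] for nm in item}
        )
        bad = np.isnan(nulls)
        n_dropped = int(bad.sum())
        if n_dropped > MAX_DROP_FRACTION * len(nulls):
            raise ValidationError(
                f"{n_dropped}/{len(nulls)} null draws undefined for {item} "
                f"(> {MAX_DROP_FRACTION:.0%})"
            )
        nulls = nulls[~bad]
        results.append(
            MixingResult(
                statistic_name=statistic,
                annotation=item,
                empirical=float(emp),
                null_values=nulls,
                z=z_score(emp, nulls),
                p=perm_pvalue(emp, nulls),
                n_dropped=n_dropped,
            )
        )
    qs = by_fdr([r.p for r in results])
    for r, q in zip(results, qs):
        r.q = float(q)
    return results


def distance_threshold_profile(
    conn: AnnotatedConnectome,
    annotation: str,
    ensemble: NullEnsemble,
    percentiles,
) -> ZProfile:
    """z-assortativity after progressively removing the shortest edges.

    The surrogate annotations are fixed; only the graph is thresholded at
    each percentile. A percentile that empties the graph truncates the
    profile with a warning.
    """
    percentiles = np.asarray(percentiles, dtype=float)
    if percentiles[0] != 0:
        raise ValueError("percentile grid must start at 0")
    zs, ps, emps, kept = [], [], [], []
    X = ensemble.draws[annotation]
    for pct in percentiles:
        try:
            sub = conn if pct == 0 else threshold_by_distance(conn, pct)
        except ValidationError:
            warnings.warn(
                f"graph empty at percentile {pct}; profile truncated", stacklevel=2
            )
            break
        emp = mixing.assortativity(sub, annotation)
        nulls = _assortativity_many(sub, X)
        nulls = nulls[~np.isnan(nulls)]
        zs.append(z_score(emp, nulls))
        ps.append(perm_pvalue(emp, nulls))
        emps.append(emp)
        kept.append(pct)
    return ZProfile(
        percentiles=np.array(kept),
        z_values=np.array(zs),
        p_values=np.array(ps),
        empirical=np.array(emps),
    )


def _pearson_rows(target: np.ndarray, maps: np.ndarray) -> np.ndarray:
    tc = target - target.mean()
    mc = maps - maps.mean(axis=0, keepdims=True)
    num = tc @ mc
    den = np.sqrt((tc @ tc) * (mc**2).sum(axis=0))
    return num / den


def decode_categories(
    target_map,
    term_maps,
    term_categories,
    n_perm: int = 10000,
    seed: int = 0,
) -> pd.DataFrame:
    """Category-level decoding of a nodal map against term maps.

    Correlates the target map with every term map, averages the
    correlations within term categories, and tests each category mean by
    permuting the term-to-category assignment ``n_perm`` times (two-sided,
    deviation from the permutation mean, BY-corrected across categories).
    """
    target = np.asarray(target_map, dtype=float)
    maps = np.asarray(term_maps, dtype=float)
    cats = np.asarray(term_categories)
    if maps.shape != (len(target), len(cats)):
        raise ValidationError(
            f"term_maps shape {maps.shape} does not match "
            f"(n={len(target)}, T={len(cats)})"
        )
    uniq, inv = np.unique(cats, return_inverse=True)
    counts = np.bincount(inv)
    if np.any(counts == 0):
        raise ValidationError("category with zero terms")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    r = _pearson_rows(target, maps)
    obs = np.array([r[inv == k].mean() for k in range(len(uniq))])
    rng = np.random.default_rng(seed)
    null_means = np.empty((n_perm, len(uniq)))
    for t in range(n_perm):
        perm_inv = inv[rng.permutation(len(inv))]
        sums = np.bincount(perm_inv, weights=r, minlength=len(uniq))
        null_means[t] = sums / counts
    p = np.array(
        [perm_pvalue(obs[k], null_means[:, k]) for k in range(len(uniq))]
    )
    q = by_fdr(p)
    return pd.DataFrame(
        {
            "category": uniq,
            "n_terms": counts,
            "mean_r": obs,
            "p": p,
            "q": q,
        }
    )


def correlate_with_nodal_property(
    values_a, values_b, ensemble_a: NullEnsemble = None
):
    """Pearson correlation of two nodal maps with permutation or analytic p.

    Undefined entries are excluded pairwise. If a null ensemble for the
    first map is supplied, p is a two-sided permutation p-value from
    recomputing r with each surrogate; otherwise the analytic p is used.
    """
    from scipy import stats

    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    mask = ~(np.isnan(a) | np.isnan(b))
    if mask.sum() < 3:
        raise ValidationError("need at least 3 paired defined values")
    r = float(np.corrcoef(a[mask], b[mask])[0, 1])
    if ensemble_a is None:
        p = float(stats.pearsonr(a[mask], b[mask]).pvalue)
        return r, p
    if len(ensemble_a.draws) != 1:
        raise ValueError("ensemble_a must hold surrogates for exactly one map")
    X = next(iter(ensemble_a.draws.values()))[:, mask]
    null_r = _pearson_rows(b[mask], X.T)
    return r, perm_pvalue(r, null_r)
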