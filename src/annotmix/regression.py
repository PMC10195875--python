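"""Edge-level weighted least squares and dominance analysis.

The response is one endpoint's annotation (``y^(j)``), the predictors the
other endpoint's annotations (``x_1^(i)``, ..., ``x_p^(i)``), and the
observation weights the connection strengths. Dominance analysis averages
the incremental weighted R-squared each predictor contributes over every
submodel, which decomposes the full-model R-squared exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .connectome import EdgeTable, ValidationError

_RANK_TOL = 1e-10
MAX_DOMINANCE_PREDICTORS = 15


@dataclass
class RegressionFit:
    intercept: float
    coefficients: dict
    weighted_r2: float
    residuals: np.ndarray
    weights: np.ndarray
    standardized: bool


@dataclass
class DominanceResult:
    total_dominance: dict
    full_model_r2: float


def _weighted_standardize(col: np.ndarray, w: np.ndarray):
    sw = w.sum()
    mu = w @ col / sw
    sd = np.sqrt(w @ (col - mu) ** 2 / sw)
    if sd <= 0:
        raise ValidationError("constant predictor column")
    return (col - mu) / sd


def _design(edges: EdgeTable, response: str, predictors):
    y = edges.endpoint_values(response)[1]  # endpoint j
    X = np.column_stack([edges.endpoint_values(p)[0] for p in predictors])
    return y, X, edges.weight


def wls_fit(
    edges: EdgeTable, response: str, predictors, standardize: bool = True
) -> RegressionFit:
    """Weighted least squares of ``y^(j)`` on ``x^(i)`` with weights ``a_ij``.

    Predictors are standardized with the edge weights by default so
    coefficients are comparable across annotations.
    """
    predictors = list(predictors)
    y, X, w = _design(edges, response, predictors)
    if len(y) < len(predictors) + 2:
        raise ValidationError("need at least #predictors + 2 edges")
    if standardize:
        X = np.column_stack([_weighted_standardize(c, w) for c in X.T])
    Xa = np.column_stack([np.ones(len(y)), X])
    sw = np.sqrt(w)
    Q = sw[:, None] * Xa
    rank = np.linalg.matrix_rank(Q, tol=_RANK_TOL * max(1.0, np.abs(Q).max()))
    if rank < Xa.shape[1]:
        # name a collinear column by testing leave-one-in ranks
        for k, name in enumerate(predictors):
            sub = np.delete(Xa, k + 1, axis=1)
            if np.linalg.matrix_rank(sw[:, None] * sub) == rank:
                raise ValidationError(
                    f"design matrix is rank deficient; predictor {name!r} "
                    "is collinear with the others"
                )
        raise ValidationError("design matrix is rank deficient")
    beta, *_ = np.linalg.lstsq(Q, sw * y, rcond=None)
    resid = y - Xa @ beta
    swsum = w.sum()
    ybar = w @ y / swsum
    ss_tot = w @ (y - ybar) ** 2
    ss_res = w @ resid**2
    r2 = 1.0 - ss_res / ss_tot
    return RegressionFit(
        intercept=float(beta[0]),
        coefficients={p: float(b) for p, b in zip(predictors, beta[1:])},
        weighted_r2=float(r2),
        residuals=resid,
        weights=w,
        standardized=standardize,
    )


def _r2_from_gram(G, g, ss_tot):
    """Weighted R-squared of a submodel from precomputed cross-products.

    G is the (1+p)x(1+p) weighted Gram of the augmented design, g the
    weighted cross-product with the centered response.
    """
    beta = np.linalg.solve(G, g)
    return float(beta @ g / ss_tot)


def dominance(
    edges: EdgeTable, response: str, predictors, standardize: bool = True
) -> DominanceResult:
    """Total dominance of each predictor: mean incremental weighted R².

    Fits all ``2^p - 1`` nonempty predictor subsets; the total dominance of
    a variable averages, over subset sizes, the mean R² gain from adding it
    to each submodel lacking it. The shares sum to the full-model R².
    """
    predictors = list(predictors)
    p = len(predictors)
    if p > MAX_DOMINANCE_PREDICTORS:
        raise ValueError(f"dominance limited to {MAX_DOMINANCE_PREDICTORS} predictors")
    y, X, w = _design(edges, response, predictors)
    if standardize:
        X = np.column_stack([_weighted_standardize(c, w) for c in X.T])
    sw = w.sum()
    ybar = w @ y / sw
    yc = y - ybar
    ss_tot = w @ yc**2
    Xa = np.column_stack([np.ones(len(y)), X])
    G_full = Xa.T @ (w[:, None] * Xa)
    g_full = Xa.T @ (w * yc)

    def r2(subset):
        if not subset:
            return 0.0
        cols = [0] + [k + 1 for k in subset]
        G = G_full[np.ix_(cols, cols)]
        try:
            return _r2_from_gram(G, g_full[cols], ss_tot)
        except np.linalg.LinAlgError:
            raise ValidationError(
                f"singular submodel for predictors {[predictors[k] for k in subset]}"
            )

    cache = {(): 0.0}
    for size in range(1, p + 1):
        for subset in combinations(range(p), size):
            cache[subset] = r2(subset)
    full_r2 = cache[tuple(range(p))]

    total = {}
    for v in range(p):
        others = [k for k in range(p) if k != v]
        level_means = []
        for size in range(0, p):
            gains = []
            for subset in combinations(others, size):
                base = cache[subset]
                with_v = cache[tuple(sorted(subset + (v,)))]
                gains.append(with_v - base)
            level_means.append(np.mean(gains))
        total[predictors[v]] = float(np.mean(level_means))
    return DominanceResult(total_dominance=total, full_model_r2=float(full_r2))
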