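"""Surrogate annotation ensembles preserving spatial autocorrelation.

Three generators:

* :func:`spin_nulls` — random rotations of spherical parcel centroids,
  mirrored across hemispheres, with nearest-centroid reassignment.
* :func:`moran_nulls` — Moran spectral randomization on the inverse
  distance weight matrix ``W`` (``w_ij = 1/d_ij``): random sign flips of
  the map's loadings on the eigenvectors of the doubly centered ``W``.
  This scheme preserves Moran's I of the map exactly (the spectral power
  per eigenvector is invariant under sign flips) and, after rescaling,
  the empirical mean and variance to ~1e-8.
* :func:`burt_nulls` — permute, smooth with a distance kernel over nearest
  neighbors, and rescale via ``y = |beta|^(1/2) x + |alpha|^(1/2) z`` with
  (alpha, beta) fit by least squares between the binned variograms of the
  original and smoothed-permuted maps.

All generators are deterministic given a seed, operate per hemisphere with
a shared per-draw seed so that homotopy is preserved, and can run jointly
(identical spatial transform for all annotations within a draw) so that
inter-map correlations survive into the null.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .connectome import AnnotatedConnectome, ValidationError

_UNIT_TOL = 1e-8


@dataclass
class SphereParcellation:
    """Unit-sphere parcel centroids per hemisphere, mapped to node indices."""

    centroids_L: np.ndarray  # (nL, 3) unit vectors
    centroids_R: np.ndarray  # (nR, 3) unit vectors
    nodes_L: np.ndarray  # node indices for centroids_L rows
    nodes_R: np.ndarray

    def __post_init__(self):
        for name in ("centroids_L", "centroids_R"):
            c = np.asarray(getattr(self, name), dtype=float)
            if c.size and np.abs(np.linalg.norm(c, axis=1) - 1).max() > _UNIT_TOL:
                raise ValidationError(f"{name} are not unit vectors")
            setattr(self, name, c)
        self.nodes_L = np.asarray(self.nodes_L, dtype=int)
        self.nodes_R = np.asarray(self.nodes_R, dtype=int)

    @property
    def n_parcels(self) -> int:
        return len(self.nodes_L) + len(self.nodes_R)


@dataclass
class NullEnsemble:
    """Stack of surrogate annotation vectors, one reference per statistic."""

    method: str  # {spin, moran, burt, naive}
    draws: dict  # annotation name -> (n_nulls, n) array
    seed: int
    n_nulls: int
    joint: bool
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        for name, arr in self.draws.items():
            if arr.shape[0] != self.n_nulls:
                raise ValidationError(
                    f"draws for {name!r} have {arr.shape[0]} rows, expected {self.n_nulls}"
                )

    @property
    def annotation_names(self):
        return list(self.draws)

    def save(self, path):
        """Serialize to an .npz container with metadata."""
        np.savez(
            path,
            method=self.method,
            seed=self.seed,
            n_nulls=self.n_nulls,
            joint=self.joint,
            names=np.array(list(self.draws), dtype=object),
            **{f"draws_{k}": v for k, v in self.draws.items()},
        )

    @classmethod
    def load(cls, path) -> "NullEnsemble":
        f = np.load(path, allow_pickle=True)
        names = list(f["names"])
        return cls(
            method=str(f["method"]),
            draws={k: f[f"draws_{k}"] for k in names},
            seed=int(f["seed"]),
            n_nulls=int(f["n_nulls"]),
            joint=bool(f["joint"]),
        )


@dataclass
class VariogramFit:
    """Least-squares fit of surrogate to empirical binned variograms."""

    alpha: float
    beta: float
    bin_centers: np.ndarray
    empirical_variogram: np.ndarray
    surrogate_variogram: np.ndarray

    @property
    def residual(self) -> float:
        d = self.empirical_variogram - (
            np.abs(self.beta) * self.surrogate_variogram + np.abs(self.alpha)
        )
        return float(d @ d)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random 3D rotation via QR decomposition of a Gaussian matrix."""
    m = rng.standard_normal((3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


# reflection across the sagittal plane: mirrors a left-hemisphere rotation
# onto the right hemisphere so homotopy is preserved
_MIRROR = np.diag([-1.0, 1.0, 1.0])


def spin_nulls(
    parc: SphereParcellation,
    annotations: dict,
    n_nulls: int,
    seed: int,
    rotation_fn=None,
) -> NullEnsemble:
    """Rotation-based surrogate maps on parcel centroids.

    Per draw, one uniform random rotation is applied to the left-hemisphere
    centroids and its sagittal mirror to the right; each parcel then takes
    the value of the nearest rotated parcel. Duplicate assignments (and
    dropped parcels) are permitted. The identical rotation is used for
    every annotation in a draw, so the ensemble is joint.

    ``rotation_fn(rng) -> 3x3 array`` is a test hook; the identity rotation
    reproduces the empirical maps exactly.
    """
    if n_nulls < 1:
        raise ValueError("n_nulls must be >= 1")
    annotations = {k: np.asarray(v, dtype=float) for k, v in annotations.items()}
    for name, vec in annotations.items():
        if len(vec) <= max(
            parc.nodes_L.max(initial=-1), parc.nodes_R.max(initial=-1)
        ):
            raise ValidationError(f"annotation {name!r} lacks values for some parcels")
    rng = np.random.default_rng(seed)
    rot = rotation_fn if rotation_fn is not None else random_rotation
    hemis = []
    if len(parc.nodes_L):
        hemis.append((parc.centroids_L, parc.nodes_L, False))
    if len(parc.nodes_R):
        hemis.append((parc.centroids_R, parc.nodes_R, True))
    if not hemis:
        raise ValidationError("parcellation has no parcels")
    names = list(annotations)
    draws = {nm: np.empty((n_nulls, len(annotations[nm]))) for nm in names}
    for nm in names:  # unannotated nodes keep their value
        draws[nm][:] = annotations[nm][None, :]
    for t in range(n_nulls):
        R = rot(rng)
        for centroids, nodes, mirror in hemis:
            Rh = _MIRROR @ R @ _MIRROR if mirror else R
            rotated = centroids @ Rh.T
            # for each original centroid, the nearest rotated centroid is
            # the source parcel whose value it receives
            _, src = cKDTree(rotated).query(centroids)
            for nm in names:
                draws[nm][t, nodes] = annotations[nm][nodes[src]]
    return NullEnsemble(
        method="spin", draws=draws, seed=seed, n_nulls=n_nulls, joint=True
    )


def morans_i(W: np.ndarray, x: np.ndarray) -> float:
    """Moran's I spatial autocorrelation of ``x`` under weights ``W``."""
    W = np.asarray(W, dtype=float)
    x = np.asarray(x, dtype=float)
    n = len(x)
    if np.any(np.diag(W) != 0):
        raise ValidationError("W must have zero diagonal")
    if np.any(W < 0):
        raise ValidationError("W must be non-negative")
    xc = x - x.mean()
    denom = xc @ xc
    if denom <= 0:
        raise ValidationError("constant x has undefined Moran's I")
    return float(n / W.sum() * (xc @ W @ xc) / denom)


def inverse_distance_weights(distances: np.ndarray, row_standardize: bool = False):
    """``w_ij = 1/d_ij`` with zero diagonal; errors on zero off-diagonal distance."""
    d = np.asarray(distances, dtype=float)
    off = ~np.eye(len(d), dtype=bool)
    if np.any(d[off] == 0):
        ii, jj = np.nonzero((d == 0) & off)
        raise ValidationError(
            f"zero off-diagonal distance between nodes {int(ii[0])} and {int(jj[0])}"
        )
    W = np.zeros_like(d)
    W[off] = 1.0 / d[off]
    if row_standardize:
        W /= W.sum(axis=1, keepdims=True)
    return W


def moran_basis(W: np.ndarray):
    """Eigenvectors/values of the doubly centered, symmetrized weight matrix.

    The constant direction (zero eigenvalue by construction) is dropped;
    eigenvectors are returned smoothest first (descending eigenvalue).
    """
    n = len(W)
    H = np.eye(n) - np.ones((n, n)) / n
    M = H @ ((W + W.T) / 2) @ H
    vals, vecs = np.linalg.eigh(M)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    # drop the direction closest to constant
    ones = np.ones(n) / np.sqrt(n)
    k = int(np.argmax(np.abs(vecs.T @ ones)))
    keep = np.array([i for i in range(n) if i != k])
    return vals[keep], vecs[:, keep]


def _hemi_groups(conn: AnnotatedConnectome, per_hemisphere):
    """Node index groups to randomize within.

    ``per_hemisphere=True`` splits by L/R label (same per-draw seed in each
    group preserves homotopy for mirrored geometries but distorts
    cross-hemisphere structure of non-homotopic maps); ``False`` randomizes
    the whole geometry as one block; ``None`` (auto) splits only when both
    L and R labels are present.
    """
    labels = conn.hemisphere
    if per_hemisphere is None:
        per_hemisphere = ("L" in labels) and ("R" in labels)
    if not per_hemisphere:
        return [np.arange(conn.n_nodes)]
    groups = []
    for lab in ("L", "R", "NA"):
        idx = np.nonzero(labels == lab)[0]
        if len(idx):
            groups.append(idx)
    return groups


def moran_nulls(
    conn: AnnotatedConnectome,
    annotations: dict,
    n_nulls: int,
    seed: int,
    *,
    n_modes: int = None,
    row_standardize: bool = False,
    joint: bool = False,
    per_hemisphere: bool = None,
) -> NullEnsemble:
    """Moran-spectral-randomization surrogates on ``W = 1/d``.

    Per hemisphere (using the same per-draw seed in each, preserving
    homotopy for mirrored geometries), the centered map is decomposed on
    the Moran eigenvector basis; each draw flips the signs of the loadings
    at random and rebuilds the map. With the full basis (default) this
    preserves Moran's I exactly; surrogate mean and variance are rescaled
    to the empirical values. ``n_modes`` restricts the basis to the
    smoothest modes, permuting the residual.

    Joint mode applies the identical sign flips to all annotations within
    a draw (experimental; rotation nulls are the native joint generator).
    """
    if n_nulls < 1:
        raise ValueError("n_nulls must be >= 1")
    annotations = {k: np.asarray(v, dtype=float) for k, v in annotations.items()}
    groups = _hemi_groups(conn, per_hemisphere)
    names = list(annotations)
    n = conn.n_nodes
    draws = {nm: np.empty((n_nulls, n)) for nm in names}
    for idx in groups:
        if len(idx) < 3:
            raise ValidationError("need at least 3 nodes per hemisphere")
        W = inverse_distance_weights(
            conn.distances[np.ix_(idx, idx)], row_standardize=row_standardize
        )
        vals, V = moran_basis(W)
        if n_modes is not None:
            if n_modes > V.shape[1]:
                raise ValidationError(
                    f"requested {n_modes} eigenvectors but only {V.shape[1]} available"
                )
            V = V[:, :n_modes]
        rng = np.random.default_rng(seed)  # same seed per hemisphere
        m = V.shape[1]
        signs = rng.choice([-1.0, 1.0], size=(n_nulls, m))
        perms = None
        if V.shape[1] < len(idx) - 1:
            perms = np.array([rng.permutation(len(idx)) for _ in range(n_nulls)])
        if not joint:
            signs_per = {
                nm: rng.choice([-1.0, 1.0], size=(n_nulls, m)) for nm in names
            }
        for nm in names:
            x = annotations[nm][idx]
            if np.std(x) == 0:
                raise ValidationError(
                    f"zero variance map cannot be randomized ({nm!r})"
                )
            xc = x - x.mean()
            a = V.T @ xc
            resid = xc - V @ a
            S = signs if joint else signs_per[nm]
            surro = (S * a) @ V.T
            if perms is not None:
                surro += resid[perms]
            # exact mean/variance match
            surro -= surro.mean(axis=1, keepdims=True)
            sd = surro.std(axis=1, keepdims=True)
            surro = surro / sd * x.std() + x.mean()
            draws[nm][:, idx] = surro
    return NullEnsemble(
        method="moran",
        draws=draws,
        seed=seed,
        n_nulls=n_nulls,
        joint=joint,
        params={
            "n_modes": n_modes,
            "row_standardize": row_standardize,
            "per_hemisphere": per_hemisphere,
        },
    )


# ---------------------------------------------------------------------------
# Variogram-matched (Burt-style) surrogates
# ---------------------------------------------------------------------------

def binned_variogram(values, pair_i, pair_j, bin_idx, n_bins):
    """Half mean squared difference per distance-lag bin."""
    sq = 0.5 * (values[pair_i] - values[pair_j]) ** 2
    sums = np.bincount(bin_idx, weights=sq, minlength=n_bins)
    counts = np.bincount(bin_idx, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        return sums / counts


def _smoothing_matrix(d: np.ndarray, knn: int) -> np.ndarray:
    """Row-normalized exponential kernel over each node's knn nearest neighbors."""
    n = len(d)
    K = np.zeros((n, n))
    for i in range(n):
        order = np.argsort(d[i])
        nbrs = order[1 : knn + 1]
        scale = d[i, nbrs].max()
        w = np.exp(-d[i, nbrs] / scale)
        K[i, nbrs] = w / w.sum()
    return K


DEFAULT_SMOOTHING_FRACTIONS = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9)


def variogram_pairs(d: np.ndarray, n_bins: int, truncate_pct: float, max_pairs: int = None):
    """Pair indices, lag-bin assignment and bin centers for a distance matrix.

    Only pairs up to the ``truncate_pct`` percentile of distances enter the
    variogram, so the fit targets short-range autocorrelation. Pairs beyond
    ``max_pairs`` are thinned with a deterministic stride.
    """
    nh = len(d)
    pair_i, pair_j = np.triu_indices(nh, k=1)
    pd_ = d[pair_i, pair_j]
    cut = np.percentile(pd_, truncate_pct)
    keep = pd_ <= cut
    pair_i, pair_j, pd_ = pair_i[keep], pair_j[keep], pd_[keep]
    if max_pairs is not None and len(pd_) > max_pairs:
        sel = np.linspace(0, len(pd_) - 1, max_pairs).astype(int)
        order = np.argsort(pd_, kind="stable")[sel]
        pair_i, pair_j, pd_ = pair_i[order], pair_j[order], pd_[order]
    edges = np.quantile(pd_, np.linspace(0, 1, n_bins + 1))
    bin_idx = np.clip(np.searchsorted(edges, pd_, side="right") - 1, 0, n_bins - 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return pair_i, pair_j, bin_idx, centers


def burt_nulls(
    conn: AnnotatedConnectome,
    annotation: str,
    n_nulls: int,
    seed: int,
    *,
    n_bins: int = 25,
    truncate_pct: float = 25.0,
    smoothing_fracs=DEFAULT_SMOOTHING_FRACTIONS,
    max_pairs: int = 2500,
    fixed_alpha_beta=None,
    keep_fits: bool = False,
    per_hemisphere: bool = None,
) -> NullEnsemble:
    """Variogram-matched surrogates: permute, smooth, rescale.

    Per draw the map is permuted and smoothed with an exponential distance
    kernel over each node's nearest neighbors at several neighborhood
    fractions (``smoothing_fracs``); for each fraction (alpha, beta) are
    fit by least squares between the binned variograms (``n_bins``
    equal-count lag bins, truncated at the ``truncate_pct`` distance
    percentile) of the original and the smoothed-permuted map, and the
    best-fitting scale is kept. The surrogate is

        y = |beta|^(1/2) x_smoothed + |alpha|^(1/2) z

    with fresh Gaussian noise z, rescaled to the empirical mean and
    standard deviation. Generation runs per hemisphere group (see
    ``per_hemisphere``) with the same per-draw seed.

    ``fixed_alpha_beta=(alpha, beta)`` is a test hook that pins the
    coefficients (single smoothing scale, no rescaling).
    """
    if n_nulls < 1:
        raise ValueError("n_nulls must be >= 1")
    x_full = conn.annotation(annotation)
    if np.std(x_full) == 0:
        raise ValidationError("zero variance map cannot be randomized")
    n = conn.n_nodes
    draws = np.empty((n_nulls, n))
    fits = []
    for idx in _hemi_groups(conn, per_hemisphere):
        nh = len(idx)
        knns = sorted({max(3, int(round(f * nh))) for f in smoothing_fracs})
        if nh < max(knns) + 1 or nh < 10:
            raise ValidationError(
                f"too few nodes ({nh}) for smoothing fractions {smoothing_fracs}; "
                f"need at least {max(max(knns) + 1, 10)}"
            )
        d = conn.distances[np.ix_(idx, idx)]
        x = x_full[idx]
        kernels = [_smoothing_matrix(d, k) for k in knns]
        pair_i, pair_j, bin_idx, centers = variogram_pairs(
            d, n_bins, truncate_pct, max_pairs
        )
        counts = np.bincount(bin_idx, minlength=n_bins).astype(float)
        bin_indicator = np.zeros((len(bin_idx), n_bins))
        bin_indicator[np.arange(len(bin_idx)), bin_idx] = 1.0
        v_emp = binned_variogram(x, pair_i, pair_j, bin_idx, n_bins)
        rng = np.random.default_rng(seed)  # same seed per hemisphere
        perms = np.array([rng.permutation(nh) for _ in range(n_nulls)])
        Z = rng.standard_normal((n_nulls, nh))
        XP = x[perms]
        if fixed_alpha_beta is not None:
            alpha = np.full(n_nulls, float(fixed_alpha_beta[0]))
            beta = np.full(n_nulls, float(fixed_alpha_beta[1]))
            SM = XP @ kernels[0].T
        else:
            best_sse = np.full(n_nulls, np.inf)
            alpha = np.empty(n_nulls)
            beta = np.empty(n_nulls)
            SM = np.empty_like(XP)
            v_best = np.empty((n_nulls, n_bins))
            for K in kernels:
                SM_k = XP @ K.T
                sq = 0.5 * (SM_k[:, pair_i] - SM_k[:, pair_j]) ** 2
                v_sm = (sq @ bin_indicator) / counts
                # closed-form 2-parameter least squares per draw
                sx = v_sm.sum(axis=1)
                sxx = (v_sm**2).sum(axis=1)
                sy = v_emp.sum()
                sxy = v_sm @ v_emp
                denom = n_bins * sxx - sx**2
                b_k = (n_bins * sxy - sx * sy) / denom
                a_k = (sy - b_k * sx) / n_bins
                resid = v_emp[None, :] - (
                    np.abs(b_k)[:, None] * v_sm + np.abs(a_k)[:, None]
                )
                sse = (resid**2).sum(axis=1)
                better = sse < best_sse
                best_sse[better] = sse[better]
                alpha[better] = a_k[better]
                beta[better] = b_k[better]
                SM[better] = SM_k[better]
                v_best[better] = v_sm[better]
            if keep_fits:
                for t in range(n_nulls):
                    fits.append(
                        VariogramFit(
                            alpha=float(alpha[t]),
                            beta=float(beta[t]),
                            bin_centers=centers,
                            empirical_variogram=v_emp,
                            surrogate_variogram=v_best[t],
                        )
                    )
        Y = (
            np.sqrt(np.abs(beta))[:, None] * SM
            + np.sqrt(np.abs(alpha))[:, None] * Z
        )
        if fixed_alpha_beta is None:
            Y -= Y.mean(axis=1, keepdims=True)
            Y = Y / Y.std(axis=1, keepdims=True) * x.std() + x.mean()
        draws[:, idx] = Y
    ens = NullEnsemble(
        method="burt",
        draws={annotation: draws},
        seed=seed,
        n_nulls=n_nulls,
        joint=False,
        params={
            "n_bins": n_bins,
            "truncate_pct": truncate_pct,
            "smoothing_fracs": tuple(smoothing_fracs),
            "per_hemisphere": per_hemisphere,
        },
    )
    if keep_fits:
        ens.params["fits"] = fits
    return ens


def naive_nulls(annotations: dict, n_nulls: int, seed: int, joint: bool = True) -> NullEnsemble:
    """Value-shuffling surrogates (no spatial structure preserved).

    The baseline the spatial generators are judged against: on spatially
    autocorrelated maps its permutation tests are anticonservative.
    """
    if n_nulls < 1:
        raise ValueError("n_nulls must be >= 1")
    annotations = {k: np.asarray(v, dtype=float) for k, v in annotations.items()}
    rng = np.random.default_rng(seed)
    names = list(annotations)
    n = len(next(iter(annotations.values())))
    draws = {nm: np.empty((n_nulls, n)) for nm in names}
    for t in range(n_nulls):
        if joint:
            perm = rng.permutation(n)
            for nm in names:
                draws[nm][t] = annotations[nm][perm]
        else:
            for nm in names:
                draws[nm][t] = annotations[nm][rng.permutation(n)]
    return NullEnsemble(
        method="naive", draws=draws, seed=seed, n_nulls=n_nulls, joint=joint
    )
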