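"""Domain types, validation, file I/O and graph manipulations.

The central object is :class:`AnnotatedConnectome`: a weighted graph whose
nodes carry spatial coordinates, pairwise distances and named annotation
vectors.  :class:`EdgeTable` expands the graph into ordered endpoint pairs
``(i, j, weight, distance)`` — the representation on which all weighted
edge-level correlations are computed.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

_SYM_RTOL = 1e-10
HEMI_LABELS = ("L", "R", "NA")


class ValidationError(ValueError):
    """Raised when an input violates a structural or numeric contract."""


@dataclass
class AnnotatedConnectome:
    """A weighted graph with node coordinates, distances and annotations.

    Parameters
    ----------
    adjacency : (n, n) ndarray
        Edge weights ``a_ij``. Zero diagonal; non-negative unless
        ``allow_negative`` was passed at construction.
    coords : (n, 3) ndarray
        Spatial positions of the nodes.
    distances : (n, n) ndarray
        Symmetric inter-node distances with zero diagonal. Euclidean
        distances of ``coords`` if not supplied.
    annotations : dict of str -> (n,) ndarray
        Named nodal annotation vectors. Missing entries are ``NaN`` and
        are never silently imputed.
    hemisphere : (n,) ndarray of str
        Labels from ``{"L", "R", "NA"}``.
    node_ids : (n,) ndarray of str
        Unique node identifiers; adjacency order is canonical.
    directed : bool
        False when the adjacency is symmetric.
    """

    adjacency: np.ndarray
    coords: np.ndarray
    distances: np.ndarray = None
    annotations: dict = field(default_factory=dict)
    hemisphere: np.ndarray = None
    node_ids: np.ndarray = None
    directed: bool = None
    allow_negative: bool = False

    def __post_init__(self):
        self.adjacency = np.asarray(self.adjacency, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        n = self.adjacency.shape[0]
        if self.adjacency.ndim != 2 or self.adjacency.shape[1] != n:
            raise ValidationError(
                f"adjacency must be square, got shape {self.adjacency.shape}"
            )
        if self.coords.shape != (n, 3):
            raise ValidationError(
                f"coords shape {self.coords.shape} does not match "
                f"adjacency shape {self.adjacency.shape}"
            )
        if not np.all(np.isfinite(self.adjacency)):
            raise ValidationError("adjacency contains non-finite entries")
        if np.any(np.diag(self.adjacency) != 0):
            idx = np.nonzero(np.diag(self.adjacency))[0]
            raise ValidationError(f"adjacency has nonzero diagonal at nodes {idx.tolist()}")
        if not self.allow_negative and np.any(self.adjacency < 0):
            ii, jj = np.nonzero(self.adjacency < 0)
            raise ValidationError(
                f"negative weight at indices {(int(ii[0]), int(jj[0]))}; "
                "pass allow_negative=True to admit signed weights"
            )
        sym = _is_symmetric(self.adjacency)
        if self.directed is None:
            self.directed = not sym
        elif not self.directed and not sym:
            raise ValidationError("directed=False but adjacency is asymmetric")
        if self.distances is None:
            self.distances = squareform(pdist(self.coords))
        else:
            self.distances = np.asarray(self.distances, dtype=float)
            if self.distances.shape != (n, n):
                raise ValidationError(
                    f"distances shape {self.distances.shape} does not match n={n}"
                )
            if not np.allclose(self.distances, self.distances.T):
                raise ValidationError("distances must be symmetric")
            if np.any(np.diag(self.distances) != 0):
                raise ValidationError("distances must have zero diagonal")
            if np.any(self.distances < 0):
                raise ValidationError("distances must be non-negative")
        if self.hemisphere is None:
            self.hemisphere = np.array(["NA"] * n, dtype=object)
        else:
            self.hemisphere = np.asarray(self.hemisphere, dtype=object)
            bad = set(self.hemisphere) - set(HEMI_LABELS)
            if bad:
                raise ValidationError(f"invalid hemisphere labels {sorted(bad)}")
            if len(self.hemisphere) != n:
                raise ValidationError("hemisphere labels length mismatch")
        if self.node_ids is None:
            self.node_ids = np.array([str(i) for i in range(n)], dtype=object)
        else:
            self.node_ids = np.asarray(self.node_ids, dtype=object)
            if len(self.node_ids) != n:
                raise ValidationError("node_ids length mismatch")
            if len(set(self.node_ids)) != n:
                seen, dup = set(), None
                for x in self.node_ids:
                    if x in seen:
                        dup = x
                        break
                    seen.add(x)
                raise ValidationError(f"duplicate node id {dup!r}")
        fixed = {}
        for name, vec in self.annotations.items():
            vec = np.asarray(vec, dtype=float)
            if vec.shape != (n,):
                raise ValidationError(
                    f"annotation {name!r} has shape {vec.shape}, expected ({n},)"
                )
            fixed[name] = vec
        self.annotations = fixed

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def strengths_out(self) -> np.ndarray:
        """Row sums of the adjacency (``k_i`` for undirected graphs)."""
        return self.adjacency.sum(axis=1)

    @property
    def strengths_in(self) -> np.ndarray:
        return self.adjacency.sum(axis=0)

    @property
    def total_weight(self) -> float:
        """Sum over all ordered endpoint pairs (``2m`` for undirected)."""
        return float(self.adjacency.sum())

    @property
    def n_edges(self) -> int:
        """Number of unordered edges (arcs, when directed)."""
        nz = int(np.count_nonzero(self.adjacency))
        return nz if self.directed else nz // 2

    def annotation(self, name: str, *, allow_missing: bool = False) -> np.ndarray:
        if name not in self.annotations:
            raise KeyError(f"unknown annotation {name!r}; have {sorted(self.annotations)}")
        vec = self.annotations[name]
        if not allow_missing and np.any(np.isnan(vec)):
            k = int(np.isnan(vec).sum())
            raise ValidationError(
                f"annotation {name!r} has {k} missing entries; "
                "drop missing nodes explicitly with drop_missing() first"
            )
        return vec

    def with_annotations(self, extra: dict) -> "AnnotatedConnectome":
        """Copy of self with additional/replaced annotation vectors."""
        out = self.copy()
        out.annotations.update(
            {k: np.asarray(v, dtype=float) for k, v in extra.items()}
        )
        return out

    def drop_missing(self, names=None) -> "AnnotatedConnectome":
        """Remove nodes (and their edges) missing in any of the given annotations."""
        names = list(self.annotations) if names is None else list(names)
        keep = np.ones(self.n_nodes, dtype=bool)
        for name in names:
            keep &= ~np.isnan(self.annotation(name, allow_missing=True))
        if keep.all():
            return self.copy()
        idx = np.nonzero(keep)[0]
        return AnnotatedConnectome(
            adjacency=self.adjacency[np.ix_(idx, idx)],
            coords=self.coords[idx],
            distances=self.distances[np.ix_(idx, idx)],
            annotations={k: v[idx] for k, v in self.annotations.items()},
            hemisphere=self.hemisphere[idx],
            node_ids=self.node_ids[idx],
            directed=self.directed,
            allow_negative=self.allow_negative,
        )

    def copy(self) -> "AnnotatedConnectome":
        return copy.deepcopy(self)


def _is_symmetric(a: np.ndarray) -> bool:
    scale = np.abs(a).max()
    if scale == 0:
        return True
    return bool(np.abs(a - a.T).max() <= _SYM_RTOL * scale)


@dataclass
class EdgeTable:
    """Ordered edge expansion of a connectome.

    For undirected graphs each unordered edge appears twice, once per
    orientation, so sums over the table reproduce sums over ordered pairs
    ``ij`` literally. ``total_weight_2m`` is the ordered weight sum (2m).
    """

    endpoint_i: np.ndarray
    endpoint_j: np.ndarray
    weight: np.ndarray
    distance: np.ndarray
    total_weight_2m: float
    strengths_out: np.ndarray
    strengths_in: np.ndarray
    source: AnnotatedConnectome

    @property
    def n_rows(self) -> int:
        return len(self.weight)

    def endpoint_values(self, name: str):
        """Annotation values at endpoints i and j of every ordered edge."""
        x = self.source.annotation(name)
        return x[self.endpoint_i], x[self.endpoint_j]


def edge_table(conn: AnnotatedConnectome) -> EdgeTable:
    """Expand every nonzero ``a_ij`` into one ordered row ``(i, j, a_ij, d_ij)``."""
    ii, jj = np.nonzero(conn.adjacency)
    if len(ii) == 0:
        raise ValidationError("no edges")
    return EdgeTable(
        endpoint_i=ii,
        endpoint_j=jj,
        weight=conn.adjacency[ii, jj],
        distance=conn.distances[ii, jj],
        total_weight_2m=conn.total_weight,
        strengths_out=conn.strengths_out,
        strengths_in=conn.strengths_in,
        source=conn,
    )


def threshold_by_distance(
    conn: AnnotatedConnectome, percentile: float
) -> AnnotatedConnectome:
    """Delete edges strictly shorter than a percentile of edge distances.

    The percentile is computed with linear interpolation over the sorted
    unordered-edge distance list; removal uses strict ``<`` so that
    ``percentile=0`` is exactly the identity and ties at the cut survive.
    Annotations, coordinates and distances are unchanged.
    """
    if not 0 <= percentile < 100:
        raise ValueError(f"percentile must be in [0, 100), got {percentile}")
    mask = conn.adjacency != 0
    if conn.directed:
        pair_mask = mask | mask.T
    else:
        pair_mask = mask
    iu = np.triu_indices(conn.n_nodes, k=1)
    pair_sel = pair_mask[iu]
    if not pair_sel.any():
        raise ValidationError("no edges")
    edge_d = conn.distances[iu][pair_sel]
    cut = np.percentile(edge_d, percentile)  # linear interpolation
    out = conn.copy()
    kill = (conn.distances < cut) & mask
    out.adjacency[kill] = 0.0
    if not conn.directed:
        out.adjacency[kill.T] = 0.0
    if not np.any(out.adjacency):
        raise ValidationError("no edges remain after distance thresholding")
    return out


# ---------------------------------------------------------------------------
# File I/O.  Adjacency: dense delimited text or 3-column edge list.
# Coordinates / annotations: CSV with header, first column the node id.
# ---------------------------------------------------------------------------

def _read_table(path) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    return pd.read_csv(path, sep=sep, float_precision="round_trip")


def _read_adjacency(path) -> np.ndarray:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    raw = pd.read_csv(path, sep=sep, header=None, float_precision="round_trip")
    arr = raw.to_numpy(dtype=float)
    if arr.ndim == 2 and arr.shape[0] == arr.shape[1]:
        return arr
    if arr.shape[1] == 3:  # edge list: i, j, w (0-based indices)
        n = int(max(arr[:, 0].max(), arr[:, 1].max())) + 1
        adj = np.zeros((n, n))
        adj[arr[:, 0].astype(int), arr[:, 1].astype(int)] = arr[:, 2]
        return adj
    raise ValidationError(
        f"adjacency file is neither square nor a 3-column edge list (shape {arr.shape})"
    )


def load_connectome(
    adjacency_path,
    coords_path,
    annotations_path=None,
    distances_path=None,
    *,
    log_weights: bool = False,
    allow_negative: bool = False,
) -> AnnotatedConnectome:
    """Load and validate a connectome from delimited text files.

    Node order in the adjacency file is canonical. Node ids are taken from
    the first column of the coordinates file (assumed to follow adjacency
    order); the annotation table is aligned to those ids.
    """
    adjacency = _read_adjacency(adjacency_path)
    n = adjacency.shape[0]
    ctab = _read_table(coords_path)
    if len(ctab) != n:
        raise ValidationError(
            f"dimension mismatch: adjacency has {n} nodes, "
            f"coordinates file has {len(ctab)} rows"
        )
    node_ids = ctab.iloc[:, 0].astype(str).to_numpy(dtype=object)
    hemisphere = None
    ccols = [c for c in ctab.columns[1:] if c.lower() != "hemisphere"]
    if "hemisphere" in [c.lower() for c in ctab.columns]:
        hcol = [c for c in ctab.columns if c.lower() == "hemisphere"][0]
        hemisphere = ctab[hcol].astype(str).to_numpy(dtype=object)
    if len(ccols) < 3:
        raise ValidationError("coordinates file must have 3 coordinate columns")
    coords = ctab[ccols[:3]].to_numpy(dtype=float)

    annotations = {}
    if annotations_path is not None:
        atab = _read_table(annotations_path)
        if len(atab) != n:
            raise ValidationError(
                f"dimension mismatch: adjacency has {n} nodes, "
                f"annotation table has {len(atab)} rows"
            )
        aids = atab.iloc[:, 0].astype(str)
        if set(aids) != set(node_ids):
            raise ValidationError("annotation node ids do not match coordinate ids")
        atab = atab.set_index(aids).loc[node_ids]
        for col in atab.columns[1:]:
            annotations[col] = atab[col].to_numpy(dtype=float)

    distances = None
    if distances_path is not None:
        distances = _read_adjacency(distances_path)

    if log_weights:
        nz = adjacency != 0
        if np.any(adjacency[nz] <= 0):
            raise ValidationError("log_weights requires strictly positive weights")
        adjacency = np.where(nz, np.log1p(adjacency), 0.0)

    return AnnotatedConnectome(
        adjacency=adjacency,
        coords=coords,
        distances=distances,
        annotations=annotations,
        hemisphere=hemisphere,
        node_ids=node_ids,
        allow_negative=allow_negative,
    )


def save_connectome(conn: AnnotatedConnectome, out_dir) -> dict:
    """Write adjacency/coords/annotations (and distances) as CSV; return paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "adjacency": out / "adjacency.csv",
        "coords": out / "coords.csv",
        "annotations": out / "annotations.csv",
        "distances": out / "distances.csv",
    }
    pd.DataFrame(conn.adjacency).to_csv(paths["adjacency"], index=False, header=False)
    ctab = pd.DataFrame(
        {
            "node_id": conn.node_ids,
            "x": conn.coords[:, 0],
            "y": conn.coords[:, 1],
            "z": conn.coords[:, 2],
            "hemisphere": conn.hemisphere,
        }
    )
    ctab.to_csv(paths["coords"], index=False)
    atab = pd.DataFrame({"node_id": conn.node_ids, **conn.annotations})
    atab.to_csv(paths["annotations"], index=False)
    pd.DataFrame(conn.distances).to_csv(paths["distances"], index=False, header=False)
    return paths
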