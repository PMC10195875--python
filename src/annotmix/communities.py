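"""Multiresolution modularity communities with consensus clustering.

Quality function::

    Q = (1/2m) sum_ij [A_ij - gamma * s_i s_j / 2m] delta(c_i, c_j)

maximized by a seeded Louvain implementation (greedy local moves plus
aggregation). Ensembles of partitions are combined by consensus clustering
on the thresholded co-assignment matrix, and partition similarity is
scored with the z-score of the Rand index (pair-counting normalization of
Traud et al.).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .connectome import AnnotatedConnectome, ValidationError


@dataclass
class Partition:
    """Node-to-community labels with the resolution and quality that produced them."""

    labels: np.ndarray
    gamma: float
    quality: float
    n_communities: int

    def __post_init__(self):
        self.labels = _relabel(np.asarray(self.labels, dtype=int))
        self.n_communities = int(self.labels.max()) + 1


def _relabel(labels: np.ndarray) -> np.ndarray:
    """Contiguous integer labels starting at 0, in order of first appearance."""
    seen = {}
    out = np.empty(len(labels), dtype=int)
    for i, lab in enumerate(labels):
        if lab not in seen:
            seen[lab] = len(seen)
        out[i] = seen[lab]
    return out


def modularity(
    conn: AnnotatedConnectome,
    labels,
    gamma: float = 1.0,
    directed_strengths: bool = False,
) -> float:
    """Evaluate the quality function on a given community assignment.

    Strengths are row sums (out-strengths for directed graphs); the
    ``directed_strengths`` option uses the out x in product instead.
    """
    labels = np.asarray(labels, dtype=int)
    if len(labels) != conn.n_nodes:
        raise ValidationError("labels length mismatch")
    A = conn.adjacency
    two_m = conn.total_weight
    s_i = conn.strengths_out
    s_j = conn.strengths_in if directed_strengths else conn.strengths_out
    same = labels[:, None] == labels[None, :]
    B = A - gamma * np.outer(s_i, s_j) / two_m
    return float(B[same].sum() / two_m)


def _local_moves(A: np.ndarray, gamma: float, rng: np.random.Generator) -> np.ndarray:
    n = len(A)
    comm = np.arange(n)
    s = A.sum(axis=1)
    two_m = A.sum()
    sigma = s.copy().astype(float)
    improved = True
    while improved:
        improved = False
        for i in rng.permutation(n):
            ci = comm[i]
            sigma[ci] -= s[i]
            nbrs = np.nonzero(A[i])[0]
            w = {ci: 0.0}
            for j in nbrs:
                if j == i:
                    continue
                w[comm[j]] = w.get(comm[j], 0.0) + A[i, j]
            best_c, best_gain = ci, w[ci] - gamma * s[i] * sigma[ci] / two_m
            for c, wc in w.items():
                if c == ci:
                    continue
                gain = wc - gamma * s[i] * sigma[c] / two_m
                if gain > best_gain + 1e-12:
                    best_c, best_gain = c, gain
            comm[i] = best_c
            sigma[best_c] += s[i]
            if best_c != ci:
                improved = True
    return _relabel(comm)


def _louvain_matrix(A: np.ndarray, gamma: float, rng: np.random.Generator) -> np.ndarray:
    """Louvain passes on a (symmetric) weight matrix; returns node labels."""
    n = len(A)
    assignment = np.arange(n)
    level = A.copy()
    while True:
        labels = _local_moves(level, gamma, rng)
        k = labels.max() + 1
        if k == len(level):
            break
        C = np.zeros((len(level), k))
        C[np.arange(len(level)), labels] = 1.0
        level = C.T @ level @ C
        assignment = labels[assignment]
        if k == 1:
            break
    return _relabel(assignment)


def louvain(conn: AnnotatedConnectome, gamma: float = 1.0, seed: int = 0) -> Partition:
    """Seeded Louvain maximization of the quality function at resolution gamma.

    Directed adjacencies are symmetrized for the move phase; the reported
    quality always evaluates the original graph.
    """
    if not np.any(conn.adjacency):
        raise ValidationError("graph has no edges")
    A = conn.adjacency
    if conn.directed:
        A = (A + A.T) / 2
    rng = np.random.default_rng(seed)
    labels = _louvain_matrix(A, gamma, rng)
    return Partition(
        labels=labels,
        gamma=gamma,
        quality=modularity(conn, labels, gamma),
        n_communities=labels.max() + 1,
    )


def coassignment_matrix(partitions) -> np.ndarray:
    """Fraction of partitions assigning each node pair to the same community."""
    L = np.array([p.labels for p in partitions])
    C = (L[:, :, None] == L[:, None, :]).mean(axis=0)
    np.fill_diagonal(C, 0.0)
    return C


def consensus_partition(
    partitions,
    tau: float = 0.5,
    seed: int = 0,
    conn: AnnotatedConnectome = None,
    n_runs: int = 10,
    max_iter: int = 50,
) -> Partition:
    """Representative partition from an ensemble via consensus clustering.

    The co-assignment probability matrix is thresholded at ``tau`` and
    re-clustered (Louvain at resolution 1) repeatedly until all runs agree
    (the thresholded co-assignment matrix is block diagonal).
    """
    partitions = list(partitions)
    if len(partitions) < 2:
        raise ValueError("need at least 2 partitions")
    n = len(partitions[0].labels)
    if any(len(p.labels) != n for p in partitions):
        raise ValidationError("partitions cover different node sets")
    gammas = {p.gamma for p in partitions}
    gamma = gammas.pop() if len(gammas) == 1 else float("nan")
    rng = np.random.default_rng(seed)
    current = partitions
    for _ in range(max_iter):
        labs = np.array([p.labels for p in current])
        if all((labs[0] == l).all() for l in labs[1:]):
            labels = labs[0]
            quality = (
                modularity(conn, labels, gamma)
                if conn is not None and np.isfinite(gamma)
                else float("nan")
            )
            return Partition(
                labels=labels,
                gamma=gamma,
                quality=quality,
                n_communities=labels.max() + 1,
            )
        C = coassignment_matrix(current)
        C[C < tau] = 0.0
        if not np.any(C):
            # no pair survives the threshold: all-singletons consensus
            current = [
                Partition(np.arange(n), gamma, float("nan"), n) for _ in range(2)
            ]
            continue
        current = [
            Partition(
                labels=_louvain_matrix(C, 1.0, rng),
                gamma=gamma,
                quality=float("nan"),
                n_communities=1,
            )
            for _ in range(n_runs)
        ]
    raise ValidationError(
        f"consensus clustering did not converge within {max_iter} iterations "
        f"(ensemble of {len(partitions)} partitions, tau={tau})"
    )


def zrand(p1: Partition, p2: Partition) -> float:
    """z-score of the Rand index under the fixed-group-size permutation null.

    Standardizes the count of node pairs co-assigned in both partitions by
    its hypergeometric expectation and variance (pair-counting
    normalization of Traud, Kelsic, Mucha & Porter).
    """
    l1, l2 = p1.labels, p2.labels
    if len(l1) != len(l2):
        raise ValidationError("partitions cover different node sets")
    n = len(l1)
    M = n * (n - 1) / 2
    sizes1 = np.bincount(l1)
    sizes2 = np.bincount(l2)
    M1 = float((sizes1 * (sizes1 - 1) / 2).sum())
    M2 = float((sizes2 * (sizes2 - 1) / 2).sum())
    cont = np.zeros((sizes1.size, sizes2.size))
    np.add.at(cont, (l1, l2), 1)
    w = float((cont * (cont - 1) / 2).sum())
    mean_w = M1 * M2 / M
    c1 = n * (n**2 - 3 * n - 2) - 8 * (n + 1) * M1 + 4 * float((sizes1**3).sum())
    c2 = n * (n**2 - 3 * n - 2) - 8 * (n + 1) * M2 + 4 * float((sizes2**3).sum())
    a1 = 4 * M1 - 2 * M
    a2 = 4 * M2 - 2 * M
    var_w = (
        M / 16
        - (a1**2) * (a2**2) / (256 * M**2)
        + c1 * c2 / (16 * n * (n - 1) * (n - 2))
        + ((a1**2 - 4 * c1 - 4 * M) * (a2**2 - 4 * c2 - 4 * M))
        / (64 * n * (n - 1) * (n - 2) * (n - 3))
    )
    if var_w <= 0:
        raise ValidationError("degenerate partitions: zero variance of the Rand index")
    return float((w - mean_w) / np.sqrt(var_w))


def gamma_scan(
    conn: AnnotatedConnectome,
    gamma_grid,
    runs_per_gamma: int = 100,
    tau: float = 0.5,
    seed: int = 0,
):
    """Consensus partitions over a resolution grid plus their zrand similarity.

    Per resolution, ``runs_per_gamma`` seeded Louvain runs are combined by
    consensus clustering. The pairwise zrand matrix over the consensus
    partitions supports selecting resolutions whose partitions persist
    across the grid (degenerate comparisons are NaN).
    """
    gamma_grid = list(gamma_grid)
    if not gamma_grid:
        raise ValueError("gamma grid is empty")
    ss = np.random.SeedSequence(seed)
    consensus = []
    for gamma in gamma_grid:
        child = ss.spawn(1)[0]
        seeds = child.generate_state(runs_per_gamma + 1)
        runs = [
            louvain(conn, gamma, seed=int(s)) for s in seeds[:runs_per_gamma]
        ]
        if runs_per_gamma == 1:
            consensus.append(runs[0])
        else:
            consensus.append(
                consensus_partition(runs, tau=tau, seed=int(seeds[-1]), conn=conn)
            )
    K = len(consensus)
    sim = np.full((K, K), np.nan)
    for a in range(K):
        for b in range(a, K):
            try:
                sim[a, b] = sim[b, a] = zrand(consensus[a], consensus[b])
            except ValidationError:
                pass
    return consensus, sim


def community_summary(
    conn: AnnotatedConnectome, partition: Partition, nodal_maps: dict
):
    """Per-community means of nodal maps (undefined entries excluded pairwise)."""
    import pandas as pd

    labels = partition.labels
    rows = []
    for c in range(partition.n_communities):
        members = labels == c
        row = {"community": c, "n_nodes": int(members.sum())}
        for name, vals in nodal_maps.items():
            vals = np.asarray(vals, dtype=float)[members]
            defined = ~np.isnan(vals)
            row[name] = float(vals[defined].mean()) if defined.any() else np.nan
        rows.append(row)
    return pd.DataFrame(rows)
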