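"""Community extraction: path weights, weight updates and sparse SVD.

Three pieces of the C-step live here.  From a current network estimate, a
pairwise weight matrix ``W1`` is built from shortest-path lengths,
``w1_ij = (p_ij / p0)^2``: gene pairs close in the network get small weight
(cheap to keep in the low-rank block), distant pairs get large weight.  The
Block PCA output ``L*`` is turned into the inference weight matrix by
``W = 1 - L*`` after normalizing ``L*`` to [0, 1], so entries inside
detected communities are penalized weakly at the next N-step.  Finally,
communities are read off ``L*`` by sparse singular value decomposition:
sequential rank-1 layers with soft-thresholded singular vectors, whose
supports define the (disjoint) gene groups; genes captured by no layer are
reported as outliers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.csgraph import shortest_path as _csgraph_shortest_path

__all__ = [
    "PathWeightMatrix",
    "CommunityPartition",
    "GraphStats",
    "shortest_path_weights",
    "update_weight_matrix",
    "ssvd_communities",
    "graph_stats",
    "overlap_counts",
    "best_community_overlap",
]


@dataclass
class PathWeightMatrix:
    """Nonnegative pairwise weights ``(p_ij / p0)^2`` with zero diagonal."""

    W1: np.ndarray
    p0: float

    def __post_init__(self) -> None:
        self.W1 = np.asarray(self.W1, dtype=float)
        if np.any(self.W1 < 0):
            raise ValueError("weights must be nonnegative")
        if np.any(np.diag(self.W1) != 0):
            raise ValueError("diagonal must be zero")
        if self.p0 <= 0:
            raise ValueError("p0 must be positive")


@dataclass
class CommunityPartition:
    """Disjoint gene groups plus unassigned outliers (0-based indices)."""

    groups: list[list[int]] = field(default_factory=list)
    outliers: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for g in self.groups:
            s = set(g)
            if s & seen:
                raise ValueError("groups must be disjoint")
            seen |= s
        if seen & set(self.outliers):
            raise ValueError("outliers must not appear in any group")

    @property
    def n_genes(self) -> int:
        return sum(len(g) for g in self.groups) + len(self.outliers)

    def labels(self, n: int) -> np.ndarray:
        """Per-gene community id; -1 marks outliers/unassigned."""
        lab = -np.ones(n, dtype=int)
        for c, g in enumerate(self.groups):
            lab[list(g)] = c
        return lab


@dataclass
class GraphStats:
    n_vertices: int
    n_arcs: int
    density: float
    diameter: int


def _undirected_lengths(support: np.ndarray) -> np.ndarray:
    """All-pairs unweighted shortest-path lengths on the undirected view."""
    S = np.asarray(support).astype(bool)
    np.fill_diagonal(S, False)
    und = (S | S.T).astype(float)
    return _csgraph_shortest_path(und, method="D", directed=False, unweighted=True)


def shortest_path_weights(
    support: np.ndarray,
    p0_fraction: float = 0.25,
    p0: float | None = None,
) -> PathWeightMatrix:
    """Build the pairwise weight matrix ``w1_ij = (p_ij / p0)^2``.

    ``p_ij`` is the unweighted shortest-path length between genes ``i`` and
    ``j`` on the undirected view of the support; disconnected pairs are
    capped at ``p_ij = n``.  ``p0`` defaults to ``p0_fraction`` times the
    network diameter (the longest finite path length).

    Raises
    ------
    ValueError
        If the support has no edges (the diameter is undefined).
    """
    P = _undirected_lengths(support)
    n = P.shape[0]
    finite = P[np.isfinite(P) & (P > 0)]
    if finite.size == 0:
        raise ValueError("support has no edges; diameter undefined")
    diameter = float(finite.max())
    if p0 is None:
        p0 = p0_fraction * diameter
    if p0 <= 0:
        raise ValueError("p0 must be positive")
    P = np.where(np.isfinite(P), P, float(n))
    W1 = (P / p0) ** 2
    np.fill_diagonal(W1, 0.0)
    return PathWeightMatrix(W1, float(p0))


def update_weight_matrix(L_star: np.ndarray) -> np.ndarray:
    """Inference weights from the community matrix: ``W = 1 - L*``.

    ``L*`` is first normalized into [0, 1]: negative entries are clipped to
    zero and, if the maximum exceeds 1, the matrix is divided by it.  The
    result keeps ``W`` nonnegative (entries in [0, 1]): zero inside strong
    community blocks, one far from any community.
    """
    L = np.clip(np.asarray(L_star, dtype=float), 0.0, None)
    mx = L.max() if L.size else 0.0
    if mx > 1.0:
        L = L / mx
    return 1.0 - L


def _sparse_power_triplet(
    R: np.ndarray, sparsity_level: float, n_iter: int = 60
) -> tuple[float, np.ndarray, np.ndarray]:
    """Leading sparse rank-1 layer of ``R`` by thresholded power iteration.

    Alternates ``u ~ R v`` and ``v ~ R^T u`` with hard zeroing below
    ``sparsity_level`` times the vector's max magnitude.  The iteration is
    seeded from the row of largest norm, which pins the layer to a single
    block even when several blocks tie in singular value (a plain SVD
    returns an arbitrary mixture of tied blocks; thresholding a mixture
    would glue them into one community).
    """
    norms = np.linalg.norm(R, axis=1)
    j = int(np.argmax(norms))
    if norms[j] <= 0:
        return 0.0, np.zeros(R.shape[0]), np.zeros(R.shape[1])
    v = R[j] / norms[j]
    u = np.zeros(R.shape[0])
    for _ in range(n_iter):
        u = R @ v
        mx = np.abs(u).max()
        if mx <= 0:
            break
        u = np.where(np.abs(u) >= sparsity_level * mx, u, 0.0)
        u /= np.linalg.norm(u)
        v = R.T @ u
        mx = np.abs(v).max()
        if mx <= 0:
            break
        v = np.where(np.abs(v) >= sparsity_level * mx, v, 0.0)
        v /= np.linalg.norm(v)
    sigma = float(u @ R @ v)
    return abs(sigma), u, v


def ssvd_communities(
    L: np.ndarray,
    max_rank: int | None = None,
    sparsity_level: float = 0.2,
    sigma_floor: float = 0.1,
) -> CommunityPartition:
    """Extract disjoint communities from a low-rank matrix by sparse SVD.

    Sequential rank-1 deflation: at each step the leading singular triplet
    ``(sigma, u, v)`` is computed, both singular vectors are hard-zeroed
    below ``sparsity_level`` times their own max magnitude (a soft sparsity
    proxy), the layer's community is the support of either thresholded
    vector, and the thresholded layer ``sigma * u_t v_t^T`` is subtracted
    before the next step.  Extraction stops at ``max_rank`` layers or when
    the leading singular value drops below ``sigma_floor`` times the first
    one.  Genes claimed by several layers go to the layer where their
    absolute loading is largest; genes claimed by none are outliers.
    """
    L = np.asarray(L, dtype=float)
    n = L.shape[0]
    if L.shape != (n, n):
        raise ValueError("L must be square")
    if max_rank is None:
        max_rank = n
    R = L.copy()
    loadings: list[np.ndarray] = []
    sigma0 = None
    for _ in range(max_rank):
        sigma, u, v = _sparse_power_triplet(R, sparsity_level)
        if sigma0 is None:
            if sigma <= 1e-12:
                break
            sigma0 = sigma
        elif sigma < sigma_floor * sigma0:
            break
        ut = np.where(np.abs(u) >= sparsity_level * np.abs(u).max(), u, 0.0)
        vt = np.where(np.abs(v) >= sparsity_level * np.abs(v).max(), v, 0.0)
        load = np.maximum(np.abs(ut), np.abs(vt))
        if not np.any(load > 0):
            break
        loadings.append(load)
        R = R - sigma * np.outer(ut, vt)
    if not loadings:
        return CommunityPartition(groups=[], outliers=list(range(n)))
    M = np.stack(loadings)  # layers x genes
    best = np.argmax(M, axis=0)
    claimed = M.max(axis=0) > 0
    groups = []
    for layer in range(M.shape[0]):
        members = sorted(np.nonzero(claimed & (best == layer))[0].tolist())
        if members:
            groups.append(members)
    outliers = sorted(np.nonzero(~claimed)[0].tolist())
    return CommunityPartition(groups=groups, outliers=outliers)


def graph_stats(support: np.ndarray) -> GraphStats:
    """Vertex/arc counts, density ``arcs / n^2`` and undirected diameter.

    Self-loops are excluded from the arc count; the density denominator is
    ``n^2``.  The diameter is the longest finite shortest-path length on
    the undirected view of the support.
    """
    S = np.asarray(support).astype(bool)
    n = S.shape[0]
    off = S.copy()
    np.fill_diagonal(off, False)
    arcs = int(off.sum())
    P = _undirected_lengths(S)
    finite = P[np.isfinite(P) & (P > 0)]
    diameter = int(finite.max()) if finite.size else 0
    return GraphStats(
        n_vertices=n, n_arcs=arcs, density=arcs / (n * n), diameter=diameter
    )


def overlap_counts(est: CommunityPartition, true: CommunityPartition) -> np.ndarray:
    """Matrix of intersection sizes |est_i ∩ true_j| between group lists."""
    out = np.zeros((len(est.groups), len(true.groups)), dtype=int)
    for i, a in enumerate(est.groups):
        sa = set(a)
        for j, b in enumerate(true.groups):
            out[i, j] = len(sa & set(b))
    return out


def best_community_overlap(
    est: CommunityPartition, true: CommunityPartition
) -> list[int]:
    """For each true community, the largest overlap with any estimated one."""
    if not est.groups:
        return [0] * len(true.groups)
    M = overlap_counts(est, true)
    return M.max(axis=0).tolist()
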