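"""Synthetic gene regulatory networks and simulated time-course expression.

The generative model is a linear ODE for mRNA concentrations,
``dx/dt = Cx + SFx`` with diagonal degradation ``C`` (entries ``-c_i``),
stoichiometric matrix ``S`` and linear reaction rates ``r = Fx``.  Sampling
it with a zero-order hold at interval ``dt`` gives the exact discrete map

    x_{k+1} = A x_k,   A = e^{C dt} + (e^{C dt} - I) C^{-1} S F.

A network is called (row-sum) stable when every row of ``A`` satisfies
``sum_j |a_ij| <= 1``, which bounds the induced infinity-norm and keeps
trajectories from diverging.  The generator plants sparse, signed,
community-structured support directly in ``A`` and rescales rows to a
stability margin strictly below 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm

__all__ = [
    "ODESystem",
    "NetworkSpec",
    "GRNMatrix",
    "ExpressionMatrix",
    "discretize_ode",
    "generate_network",
    "simulate_expression",
    "add_noise",
    "test1_network",
]


@dataclass
class ODESystem:
    """Continuous-time linear GRN model ``dx/dt = Cx + S r``, ``r = Fx``.

    Parameters
    ----------
    C : diagonal degradation-rate matrix with strictly negative diagonal
        (per-hour rates ``-c_i``).
    S : stoichiometric matrix (dimensionless).
    F : reaction-rate coefficient matrix (dimensionless).
    dt : sampling interval in hours.
    """

    C: np.ndarray
    S: np.ndarray
    F: np.ndarray
    dt: float

    def __post_init__(self) -> None:
        self.C = np.asarray(self.C, dtype=float)
        self.S = np.asarray(self.S, dtype=float)
        self.F = np.asarray(self.F, dtype=float)
        n = self.C.shape[0]
        for name, M in (("C", self.C), ("S", self.S), ("F", self.F)):
            if M.shape != (n, n):
                raise ValueError(f"{name} must be {n}x{n}, got {M.shape}")
        if not np.allclose(self.C, np.diag(np.diag(self.C))):
            raise ValueError("C must be diagonal")
        d = np.diag(self.C)
        if np.any(d >= 0):
            raise ValueError("C must have strictly negative diagonal")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    @property
    def n(self) -> int:
        return self.C.shape[0]


@dataclass
class GRNMatrix:
    """Discrete transition matrix of a gene regulatory network.

    ``A[i, j]`` is the (signed) influence of gene ``j`` on gene ``i`` in the
    map ``x_{k+1} = A x_k``.  Positive off-diagonal entries are promotions,
    negative ones repressions; the diagonal carries self-decay.
    """

    A: np.ndarray
    gene_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        if self.A.ndim != 2 or self.A.shape[0] != self.A.shape[1]:
            raise ValueError("A must be square")
        if not self.gene_ids:
            self.gene_ids = [f"g{i + 1}" for i in range(self.A.shape[0])]
        if len(self.gene_ids) != self.A.shape[0]:
            raise ValueError("gene_ids length must match A")

    @property
    def n(self) -> int:
        return self.A.shape[0]

    def row_l1(self) -> np.ndarray:
        return np.abs(self.A).sum(axis=1)

    def is_stable(self, tol: float = 1e-8) -> bool:
        """Row-sum stability: ``sum_j |a_ij| <= 1`` for every row."""
        return bool(np.all(self.row_l1() <= 1.0 + tol))

    def support(self, threshold: float = 1e-4, include_diagonal: bool = False) -> np.ndarray:
        """Boolean edge support at magnitude ``threshold``."""
        S = np.abs(self.A) > threshold
        if not include_diagonal:
            np.fill_diagonal(S, False)
        return S

    def n_edges(self, threshold: float = 1e-4) -> int:
        return int(self.support(threshold).sum())


@dataclass
class ExpressionMatrix:
    """Genes x time-points expression matrix.

    ``X1``/``X2`` are the first/last ``m - 1`` columns, the paired snapshots
    of the one-step regression ``A X1 ~ X2``.
    """

    X: np.ndarray
    gene_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D (genes x time points)")
        if self.X.shape[1] < 2:
            raise ValueError("need at least m = 2 time points")
        if not self.gene_ids:
            self.gene_ids = [f"g{i + 1}" for i in range(self.X.shape[0])]
        if len(self.gene_ids) != self.X.shape[0]:
            raise ValueError("gene_ids length must match X")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def m(self) -> int:
        return self.X.shape[1]

    @property
    def X1(self) -> np.ndarray:
        return self.X[:, :-1]

    @property
    def X2(self) -> np.ndarray:
        return self.X[:, 1:]


@dataclass
class NetworkSpec:
    """Recipe for a random sparse, stable, community-structured network."""

    n: int
    communities: list[list[int]] = field(default_factory=list)
    n_edges: int = 0
    within_density: float = 0.7
    between_density: float = 0.1
    sign_fraction: float = 1.0 / 3.0
    stability_margin: float = 0.95
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("need at least 2 genes")
        seen: set[int] = set()
        for grp in self.communities:
            g = set(grp)
            if not g <= set(range(self.n)):
                raise ValueError("community indices must lie in 0..n-1")
            if g & seen:
                raise ValueError("communities must be disjoint")
            seen |= g
        for name in ("within_density", "between_density", "sign_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 0.0 < self.stability_margin < 1.0:
            raise ValueError("stability_margin must be in (0, 1)")
        if self.n_edges <= 0:
            raise ValueError("n_edges must be positive")


def discretize_ode(sys: ODESystem) -> GRNMatrix:
    """Zero-order-hold discretization of the linear ODE model.

    Returns the exact one-step map ``A = e^{C dt} + (e^{C dt} - I) C^{-1} S F``.

    Raises
    ------
    ValueError
        If ``C`` is singular (a zero diagonal entry).
    """
    d = np.diag(sys.C)
    if np.any(d == 0.0) or not np.isfinite(np.linalg.cond(sys.C)):
        raise ValueError("C must be invertible")
    E = expm(sys.C * sys.dt)
    n = sys.n
    A = E + (E - np.eye(n)) @ np.diag(1.0 / d) @ sys.S @ sys.F
    return GRNMatrix(A)


def _edge_candidates(spec: NetworkSpec) -> tuple[np.ndarray, np.ndarray]:
    """Off-diagonal (i, j) candidates and their within-community mask."""
    n = spec.n
    label = -np.ones(n, dtype=int)
    for c, grp in enumerate(spec.communities):
        label[list(grp)] = c
    ii, jj = np.where(~np.eye(n, dtype=bool))
    within = (label[ii] >= 0) & (label[ii] == label[jj])
    return np.column_stack([ii, jj]), within


def generate_network(spec: NetworkSpec) -> GRNMatrix:
    """Draw a random stable sparse GRN with planted community structure.

    Edge positions are sampled without replacement from all off-diagonal
    pairs, weighting within-community pairs by ``within_density`` and all
    other pairs by ``between_density``.  Off-diagonal signs are repressive
    with probability ``sign_fraction``; diagonal self-decay entries are
    positive; each row is rescaled so its L1 norm is at most
    ``stability_margin`` (< 1), guaranteeing stability.
    """
    rng = np.random.default_rng(spec.seed)
    pairs, within = _edge_candidates(spec)
    w = np.where(within, spec.within_density, spec.between_density)
    feasible = int((w > 0).sum())
    if spec.n_edges > feasible:
        raise ValueError(
            f"cannot place {spec.n_edges} edges: only {feasible} candidate "
            "pairs have positive density"
        )
    p = w / w.sum()
    idx = rng.choice(len(pairs), size=spec.n_edges, replace=False, p=p)
    A = np.zeros((spec.n, spec.n))
    # planted edge (source j -> target i) lives at A[i, j]
    for i, j in pairs[idx]:
        mag = rng.uniform(0.25, 1.0)
        sign = -1.0 if rng.uniform() < spec.sign_fraction else 1.0
        A[j, i] = sign * mag
    np.fill_diagonal(A, rng.uniform(0.2, 0.9, size=spec.n))
    _rescale_rows(A, spec.stability_margin)
    return GRNMatrix(A)


def _rescale_rows(A: np.ndarray, margin: float) -> None:
    """Scale each row down (never up) so its L1 norm is at most ``margin``."""
    s = np.abs(A).sum(axis=1)
    scale = np.where(s > margin, margin / np.maximum(s, 1e-300), 1.0)
    A *= scale[:, None]


def simulate_expression(
    A: GRNMatrix | np.ndarray,
    x0: np.ndarray | None = None,
    m: int = 50,
    seed: int | None = None,
) -> ExpressionMatrix:
    """Simulate ``m`` time points of the discrete dynamics ``x_{k+1} = A x_k``.

    ``x0`` defaults to a uniform draw on (0, 1)^n.  Column ``k+1`` equals
    ``A`` times column ``k`` exactly (no process noise; measurement noise is
    added separately by :func:`add_noise`).
    """
    mat = A.A if isinstance(A, GRNMatrix) else np.asarray(A, dtype=float)
    n = mat.shape[0]
    if m < 2:
        raise ValueError("need m >= 2 time points")
    if x0 is None:
        x0 = np.random.default_rng(seed).uniform(0.0, 1.0, size=n)
    x0 = np.asarray(x0, dtype=float)
    if x0.shape != (n,):
        raise ValueError(f"x0 must have length {n}")
    X = np.empty((n, m))
    X[:, 0] = x0
    for k in range(m - 1):
        X[:, k + 1] = mat @ X[:, k]
    ids = A.gene_ids if isinstance(A, GRNMatrix) else []
    return ExpressionMatrix(X, list(ids))


def add_noise(
    X: ExpressionMatrix,
    fraction: float,
    sigma: float = 1.0,
    seed: int | None = None,
) -> ExpressionMatrix:
    """Perturb a random subset of entries with additive Gaussian noise.

    Exactly ``round(fraction * n * m)`` entries, chosen uniformly without
    replacement, receive independent N(0, sigma^2) noise; all other entries
    are returned bit-identical.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    Y = X.X.copy()
    k = int(round(fraction * Y.size))
    if k > 0:
        rng = np.random.default_rng(seed)
        flat = rng.choice(Y.size, size=k, replace=False)
        Y.flat[flat] += rng.normal(0.0, sigma, size=k)
    return ExpressionMatrix(Y, list(X.gene_ids))


# ---------------------------------------------------------------------------
# Canonical 14-gene benchmark network
# ---------------------------------------------------------------------------

# Signed edge list (source, target, sign), genes numbered 1..14.  This is a
# SYNTHETIC stand-in benchmark hand-constructed to match the published
# description of the small test network: 14 genes, 27 interactions, two
# communities (genes 1-5 and genes 6-10) and undirected diameter 6.  Genes
# 11-14 are peripheral.  Roughly one third of the interactions are
# repressive.
_TEST1_EDGES: list[tuple[int, int, int]] = [
    # community 1 (genes 1-5): densely wired
    (1, 2, +1), (1, 3, +1), (1, 4, +1), (1, 5, +1), (2, 3, +1),
    (2, 4, -1), (2, 5, -1), (3, 4, +1), (3, 5, -1), (4, 5, +1),
    # community 2 (genes 6-10): densely wired
    (6, 7, +1), (6, 8, +1), (6, 9, +1), (6, 10, +1), (7, 8, +1),
    (7, 9, -1), (7, 10, -1), (8, 9, +1), (8, 10, -1), (9, 10, +1),
    # peripheral genes 11-14 relay the two communities; there is no direct
    # community-to-community interaction
    (5, 11, +1), (11, 12, -1), (12, 13, +1), (13, 6, +1), (13, 7, -1),
    (6, 14, +1), (13, 14, -1),
]


def test1_network(margin: float = 0.95) -> GRNMatrix:
    """The canonical 14-gene, 27-interaction benchmark network.

    A synthetic stand-in with two planted five-gene communities (genes 1-5
    and 6-10), four peripheral genes and undirected diameter 6.  Edge
    magnitudes and self-decay rates are fixed by an internal seed so the
    network is a deterministic fixture; rows are rescaled to L1 norm at most
    ``margin``.
    """
    rng = np.random.default_rng(14027)
    A = np.zeros((14, 14))
    for s, t, sign in _TEST1_EDGES:
        A[t - 1, s - 1] = sign * rng.uniform(0.25, 1.0)
    np.fill_diagonal(A, rng.uniform(0.2, 0.9, size=14))
    _rescale_rows(A, margin)
    return GRNMatrix(A)
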