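"""Distance measures and kernel weights for medoidshift clustering.

Two distance regimes are supported: plain squared Euclidean distance in the
ambient (typically PCA-reduced) space, and geodesic-style shortest-path
distances over a neighbor graph whose edges are weighted by squared Euclidean
distance, in the spirit of ISOMAP's approximation of intrinsic manifold
distance.  The kernel weights defined here are the per-point weights of the
medoid update step: a flat ("no kernel") weight that is 1 inside the unit
neighborhood and 0 outside, and a negative-exponential weight
``K = 1 - exp(D / h)`` that penalises distant points with increasingly
negative weight, driving cluster representatives toward extreme points of
each subspace.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix, csr_matrix
from scipy.sparse.csgraph import shortest_path
from scipy.spatial.distance import cdist

__all__ = [
    "KernelSpec",
    "NeighborGraph",
    "squared_euclidean_matrix",
    "build_neighbor_graph",
    "path_distance_matrix",
    "kernel_weight",
]

#: Cap substituted for +inf path distances inside medoid objectives so that
#: the argmin stays well-defined without non-finite arithmetic.
DISTANCE_CAP = 1e12


@dataclass(frozen=True)
class KernelSpec:
    """Configuration of the per-point weight function of the medoid update.

    Parameters
    ----------
    mode:
        ``"flat"`` — the "no kernel" weight, 1 for squared distances within
        ``h**2`` and 0 outside; ``"negexp"`` — the negative-exponential
        kernel ``1 - exp(sign * D / h)``.
    h:
        Neighborhood bandwidth.  The default of 1 encodes the assumption
        that, after normalisation of every feature to [0, 1], each cluster
        is approximately unit length in its embedding space.
    c0:
        Scaling constant of the kernel density estimate.  It rescales the
        density uniformly and does not affect the argmin of the medoid
        update; kept for completeness.
    exponent_sign:
        ``"pos"`` uses the kernel exactly as stated, ``K = 1 - e^{D/h}``
        (unbounded below); ``"neg"`` uses the bounded alternative
        ``K = 1 - e^{-D/h}``.  See the methods note for why both exist.
    floor:
        Weight assigned to points at infinite (cross-component) path
        distance under ``negexp``/``pos``, standing in for the -inf limit.
    """

    mode: str = "flat"
    h: float = 1.0
    c0: float = 1.0
    exponent_sign: str = "pos"
    floor: float = -1e12

    def __post_init__(self) -> None:
        if self.mode not in ("flat", "negexp"):
            raise ValueError(f"unknown kernel mode {self.mode!r}; use 'flat' or 'negexp'")
        if self.exponent_sign not in ("pos", "neg"):
            raise ValueError(
                f"unknown exponent sign {self.exponent_sign!r}; use 'pos' or 'neg'"
            )
        if not self.h > 0:
            raise ValueError(f"bandwidth h must be > 0, got {self.h}")
        if not self.c0 > 0:
            raise ValueError(f"scale c0 must be > 0, got {self.c0}")


@dataclass
class NeighborGraph:
    """Undirected neighbor graph with squared-Euclidean edge weights.

    ``adjacency`` is a symmetric sparse matrix whose stored entries are the
    edges; explicit zeros are meaningful (duplicate points yield zero-weight
    edges) and are preserved.
    """

    adjacency: csr_matrix
    k: int | None = None
    radius: float | None = None
    edge_list: list[tuple[int, int, float]] = field(default_factory=list, repr=False)

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]


def squared_euclidean_matrix(X: np.ndarray) -> np.ndarray:
    """All-pairs squared Euclidean distances, symmetric with zero diagonal.

    Raises ``ValueError`` naming the first offending row if any entry is
    non-finite.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] < 1:
        raise ValueError("need at least one sample")
    bad = ~np.isfinite(X).all(axis=1)
    if bad.any():
        raise ValueError(f"non-finite entries in row {int(np.nonzero(bad)[0][0])}")
    D = cdist(X, X, metric="sqeuclidean")
    # enforce exact symmetry / zero diagonal against floating-point fuzz
    D = 0.5 * (D + D.T)
    np.fill_diagonal(D, 0.0)
    return D


def build_neighbor_graph(
    X: np.ndarray,
    k: int = 5,
    rule: str = "knn",
    radius: float | None = None,
) -> NeighborGraph:
    """Symmetric neighbor graph with squared-Euclidean edge weights.

    Under ``rule="knn"`` an edge {i, j} exists iff j is among i's ``k``
    nearest neighbors by Euclidean distance or vice versa; ties at the k-th
    neighbor are all included, so nominal degree may be exceeded.  Under
    ``rule="eps"`` an edge exists iff the Euclidean distance is at most
    ``radius``.  Duplicate points produce zero-weight edges, which are kept.
    """
    D = squared_euclidean_matrix(X)
    m = D.shape[0]
    if rule == "knn":
        if not 1 <= k < m:
            raise ValueError(f"k must satisfy 1 <= k < m (k={k}, m={m})")
        rows: list[int] = []
        cols: list[int] = []
        for i in range(m):
            d = D[i].copy()
            d[i] = np.inf
            kth = np.partition(d, k - 1)[k - 1]
            nbrs = np.nonzero(d <= kth)[0]  # includes all kth-distance ties
            rows.extend([i] * len(nbrs))
            cols.extend(nbrs.tolist())
    elif rule == "eps":
        if radius is None or radius <= 0:
            raise ValueError("rule='eps' requires a positive radius")
        iu, ju = np.nonzero(D <= radius**2)
        keep = iu != ju
        rows, cols = iu[keep].tolist(), ju[keep].tolist()
    else:
        raise ValueError(f"unknown neighbor rule {rule!r}; use 'knn' or 'eps'")

    # symmetrize: collect the undirected edge set
    edges = {(min(i, j), max(i, j)) for i, j in zip(rows, cols)}
    edge_list = sorted((i, j, float(D[i, j])) for i, j in edges)
    if edge_list:
        ei = np.array([e[0] for e in edge_list])
        ej = np.array([e[1] for e in edge_list])
        ew = np.array([e[2] for e in edge_list])
        adj = coo_matrix(
            (np.concatenate([ew, ew]), (np.concatenate([ei, ej]), np.concatenate([ej, ei]))),
            shape=(m, m),
        ).tocsr()
    else:
        adj = csr_matrix((m, m))
    return NeighborGraph(adjacency=adj, k=k if rule == "knn" else None,
                         radius=radius, edge_list=edge_list)


def path_distance_matrix(G: NeighborGraph) -> np.ndarray:
    """All-pairs shortest-path distances over the neighbor graph.

    Edge weights are the squared Euclidean distances between neighboring
    points; entries are +inf for node pairs in different components.
    """
    D = shortest_path(G.adjacency, method="D", directed=False, unweighted=False)
    np.fill_diagonal(D, 0.0)
    return D


def kernel_weight(D, spec: KernelSpec):
    """Per-point weight of the medoid update for distance(s) ``D``.

    ``negexp`` evaluates ``1 - exp(sign * D / h)`` (with infinite or
    overflowing distances mapped to ``spec.floor`` under the positive sign);
    ``flat`` is 1 when ``D / h**2 <= 1`` and 0 otherwise.  ``D`` may be a
    scalar or array of nonnegative (possibly infinite) distances.
    """
    arr = np.asarray(D, dtype=float)
    if np.any(arr < 0):
        raise ValueError("distances must be nonnegative")
    if spec.mode == "flat":
        w = np.where(arr / spec.h**2 <= 1.0, 1.0, 0.0)
    else:
        sign = 1.0 if spec.exponent_sign == "pos" else -1.0
        with np.errstate(over="ignore"):
            w = 1.0 - np.exp(sign * arr / spec.h)
        w = np.where(np.isfinite(w), w, spec.floor)
    if np.isscalar(D) or arr.ndim == 0:
        return float(w)
    return w


def shadow_value(t, spec: KernelSpec):
    """Shadow-kernel profile Φ(t) of the active mode, for density estimates.

    The flat weight is the derivative profile of the Epanechnikov-type
    shadow ``Φ(t) = max(0, 1 - t)``; for the negative-exponential weight the
    shadow is its antiderivative ``Φ(t) = t - h·(e^{±t/h} - 1)/(±1)`` up to
    an additive constant, used only for diagnostics.
    """
    t = np.asarray(t, dtype=float)
    if spec.mode == "flat":
        return np.maximum(0.0, 1.0 - t)
    sign = 1.0 if spec.exponent_sign == "pos" else -1.0
    with np.errstate(over="ignore"):
        val = t - (spec.h / sign) * (np.exp(sign * t / spec.h) - 1.0)
    return np.where(np.isfinite(val), val, -math.inf)
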