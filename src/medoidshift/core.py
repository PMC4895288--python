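"""The medoidshift engine: kernel density, medoid updates, and convergence.

Medoidshift is a mode-seeking clustering in which every point iteratively
moves to the *data point* (medoid) minimising a kernel-weighted sum of
distances to all points,

    y_{k+1} = argmin_y  sum_i  D(x_i, y) * w_i(y_k),

where the weights ``w_i`` come from the kernel profile evaluated at the
distance between ``x_i`` and the current candidate ``y_k``.  Because the
candidate set is finite, iterating this map either reaches a fixed point or
enters a cycle; cycles are resolved deterministically to the cycle member
with the lowest update objective.  Cluster representatives are therefore
always observed data points, which matters for interpretation: a tumor
cluster's representative is an actual tumor profile, not a synthetic mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .distances import (
    DISTANCE_CAP,
    KernelSpec,
    build_neighbor_graph,
    kernel_weight,
    path_distance_matrix,
    shadow_value,
    squared_euclidean_matrix,
)

__all__ = [
    "MedoidMap",
    "Clustering",
    "MedoidShift",
    "kernel_density",
    "medoid_step",
    "run_medoidshift",
    "extract_clusters",
]


@dataclass
class MedoidMap:
    """Converged representative (a data-point index) for every point."""

    rep: np.ndarray
    iterations: np.ndarray

    def __post_init__(self) -> None:
        m = len(self.rep)
        if m and ((self.rep < 0).any() or (self.rep >= m).any()):
            raise ValueError("representatives must be valid data-point indices")


@dataclass
class Clustering:
    """Flat cluster assignment extracted from a :class:`MedoidMap`."""

    labels: np.ndarray
    representative_of_cluster: dict[int, int]
    n_clusters: int


def _weight_matrix(D: np.ndarray, spec: KernelSpec) -> np.ndarray:
    """W[i, cur] = weight of point i in the update step anchored at cur.

    Flat mode weights are phi(D/h^2) in {0, 1}; negexp mode applies the
    kernel to the raw distance, K = 1 - e^{D/h}, as stated.
    """
    if spec.mode == "flat":
        return np.where(D / spec.h**2 <= 1.0, 1.0, 0.0)
    return np.asarray(kernel_weight(D, spec), dtype=float)


def _capped(D: np.ndarray) -> np.ndarray:
    return np.where(np.isinf(D), DISTANCE_CAP, D)


def kernel_density(i: int, D: np.ndarray, spec: KernelSpec) -> float:
    """Kernel density estimate at point ``i``: c0 * sum_j Phi(D[i,j]/h^2)."""
    t = _capped(D[i]) / spec.h**2
    return float(spec.c0 * np.sum(shadow_value(t, spec)))


def medoid_step(current: int, D: np.ndarray, spec: KernelSpec) -> int:
    """One medoid update from candidate ``current``; ties -> lowest index.

    Returns ``current`` unchanged when every weight is zero (an isolated
    point under the flat kernel has no information to move it).
    """
    w = _weight_matrix(D, spec)[:, current]
    if spec.mode == "flat" and not np.any(w):
        return int(current)
    obj = _capped(D).T @ w
    return int(np.argmin(obj))


def _next_map(D: np.ndarray, spec: KernelSpec) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised update map: nxt[cur] = medoid_step(cur) for every cur.

    Also returns the full objective matrix obj[y, cur] used for cycle
    resolution.  The update depends only on the current candidate, so the
    whole iteration is a walk on this functional graph.
    """
    W = _weight_matrix(D, spec)
    obj = _capped(D).T @ W
    nxt = np.argmin(obj, axis=0).astype(np.intp)
    if spec.mode == "flat":
        dead = ~np.any(W, axis=0)
        if dead.any():
            idx = np.nonzero(dead)[0]
            nxt[idx] = idx
    return nxt, obj


def _resolve_fixed_points(nxt: np.ndarray, obj: np.ndarray) -> np.ndarray:
    """Fixed point reached from every node of the functional graph ``nxt``.

    A cycle is collapsed to the member with the lowest update objective
    (evaluated from its predecessor in the cycle); ties break to the lowest
    index.
    """
    m = len(nxt)
    resolved = np.full(m, -1, dtype=np.intp)
    for s in range(m):
        if resolved[s] >= 0:
            continue
        path: list[int] = []
        pos: dict[int, int] = {}
        cur = s
        while True:
            if resolved[cur] >= 0:
                f = resolved[cur]
                break
            if cur in pos:
                cycle = path[pos[cur]:]
                best = None
                for t, member in enumerate(cycle):
                    pred = cycle[t - 1]  # t=0 wraps to the last member
                    val = (obj[member, pred], member)
                    if best is None or val < best:
                        best = val
                f = best[1]
                break
            pos[cur] = len(path)
            path.append(cur)
            cur = int(nxt[cur])
        for node in path:
            resolved[node] = f
    return resolved


def run_medoidshift(
    D: np.ndarray, spec: KernelSpec, single_round: bool = False
) -> MedoidMap:
    """Iterate the medoid update to a fixed point for every data point.

    Each point starts from the candidate with the smallest distance to it
    (itself, except for duplicates with a lower index) and follows the
    update map until it revisits a candidate.  With ``single_round`` only
    one update is applied — the "denoised data after one round" reading of
    the first stage.
    """
    D = np.asarray(D, dtype=float)
    m = D.shape[0]
    if m == 0:
        return MedoidMap(rep=np.empty(0, dtype=np.intp), iterations=np.empty(0, dtype=np.intp))
    y0 = np.argmin(D, axis=1).astype(np.intp)
    nxt, obj = _next_map(D, spec)
    if single_round:
        return MedoidMap(rep=nxt[y0], iterations=np.ones(m, dtype=np.intp))
    resolved = _resolve_fixed_points(nxt, obj)
    rep = resolved[y0]
    iterations = np.zeros(m, dtype=np.intp)
    for i in range(m):
        cur = int(y0[i])
        seen = set()
        steps = 0
        while cur not in seen and nxt[cur] != cur:
            seen.add(cur)
            cur = int(nxt[cur])
            steps += 1
        iterations[i] = steps
    return MedoidMap(rep=rep, iterations=iterations)


def extract_clusters(mm: MedoidMap) -> Clustering:
    """Group points by shared fixed point; labels ordered by fixed-point index."""
    fixed = np.unique(mm.rep)
    label_of = {int(f): lab for lab, f in enumerate(fixed)}
    labels = np.array([label_of[int(r)] for r in mm.rep], dtype=np.intp)
    return Clustering(
        labels=labels,
        representative_of_cluster={lab: int(f) for f, lab in ((f, label_of[int(f)]) for f in fixed)},
        n_clusters=len(fixed),
    )


class MedoidShift(ClusterMixin, BaseEstimator):
    """Medoidshift clustering with configurable distance and kernel.

    Parameters
    ----------
    kernel : {"flat", "negexp"}
        Weight function of the medoid update.  ``"flat"`` is the
        "no kernel" variant (uniform weight within the unit neighborhood);
        ``"negexp"`` is the negative-exponential kernel that pushes
        representatives to extreme points of distinct subspaces.
    h : float, default=1.0
        Neighborhood bandwidth; 1.0 assumes features normalised to [0, 1].
    c0 : float, default=1.0
        Density scale constant (does not change assignments).
    metric : {"path", "sqeuclidean"}
        ``"path"`` uses shortest-path distances over the k-NN graph with
        squared-Euclidean edge weights (ISOMAP-style intrinsic distance);
        ``"sqeuclidean"`` uses plain ambient squared Euclidean distance.
    k_nn : int, default=10
        Neighbors per point for the graph (clipped to m - 1); the default
        is chosen large enough that benchmark-scale clouds stay connected,
        as ISOMAP-style path distances assume.
    graph_rule : {"knn", "eps"}
        Neighbor-graph construction rule; ``"eps"`` uses ``radius``.
    exponent_sign : {"pos", "neg"}
        Sign of the exponent in the negative-exponential kernel.
    floor : float
        Kernel weight standing in for -inf at infinite path distance.
    single_round : bool
        Apply only one medoid update instead of iterating to convergence.

    Attributes
    ----------
    labels_ : ndarray of shape (m,)
    medoid_indices_ : ndarray — data-point index of each cluster representative.
    cluster_centers_ : ndarray — coordinates of the representatives.
    medoid_map_ : MedoidMap — per-point converged representative.
    n_clusters_ : int
    n_iter_ : int — maximum iteration count over points.
    """

    def __init__(
        self,
        kernel: str = "negexp",
        h: float = 1.0,
        c0: float = 1.0,
        metric: str = "path",
        k_nn: int = 10,
        graph_rule: str = "knn",
        radius: float | None = None,
        exponent_sign: str = "pos",
        floor: float = -1e12,
        single_round: bool = False,
    ) -> None:
        self.kernel = kernel
        self.h = h
        self.c0 = c0
        self.metric = metric
        self.k_nn = k_nn
        self.graph_rule = graph_rule
        self.radius = radius
        self.exponent_sign = exponent_sign
        self.floor = floor
        self.single_round = single_round

    def _spec(self) -> KernelSpec:
        return KernelSpec(
            mode=self.kernel,
            h=self.h,
            c0=self.c0,
            exponent_sign=self.exponent_sign,
            floor=self.floor,
        )

    def _distance_matrix(self, X: np.ndarray) -> np.ndarray:
        if self.metric == "sqeuclidean":
            return squared_euclidean_matrix(X)
        if self.metric == "path":
            m = X.shape[0]
            G = build_neighbor_graph(
                X, k=min(self.k_nn, m - 1), rule=self.graph_rule, radius=self.radius
            )
            return path_distance_matrix(G)
        raise ValueError(f"unknown metric {self.metric!r}; use 'path' or 'sqeuclidean'")

    def fit(self, X, y=None):
        X = check_array(X, ensure_min_samples=1)
        m = X.shape[0]
        if m == 1:
            self.medoid_map_ = MedoidMap(
                rep=np.zeros(1, dtype=np.intp), iterations=np.zeros(1, dtype=np.intp)
            )
        else:
            D = self._distance_matrix(X)
            self.medoid_map_ = run_medoidshift(D, self._spec(), self.single_round)
        clustering = extract_clusters(self.medoid_map_)
        self.labels_ = clustering.labels
        self.medoid_indices_ = np.array(
            [clustering.representative_of_cluster[c] for c in range(clustering.n_clusters)],
            dtype=np.intp,
        )
        self.cluster_centers_ = X[self.medoid_indices_]
        self.n_clusters_ = clustering.n_clusters
        self.n_iter_ = int(self.medoid_map_.iterations.max(initial=0))
        return self

    def predict(self, X):
        """Assign new points to the cluster of their nearest representative."""
        check_is_fitted(self, "cluster_centers_")
        X = check_array(X)
        d = squared_euclidean_matrix(np.vstack([X, self.cluster_centers_]))
        block = d[: X.shape[0], X.shape[0]:]
        return np.argmin(block, axis=1)
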