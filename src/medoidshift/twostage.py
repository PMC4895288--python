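"""Two-stage medoidshift and the two single-stage baseline variants.

The two-stage strategy separates denoising from subspace decomposition:

* **Stage 1** runs kernel-free (flat-weight) medoidshift on plain squared
  Euclidean distances in the ambient space.  Mode seeking pulls every point
  to a local center of mass, so the surviving representatives form a
  denoised, much smaller stand-in for the data.
* **Stage 2** runs medoidshift with the negative-exponential kernel on
  shortest-path (ISOMAP-style) distances over a neighbor graph built on the
  stage-1 representatives only.  The kernel drives representatives to
  extreme points of distinct subspaces, so tumors mixing different subsets
  of cell types end up in different clusters even where their point clouds
  touch.  Every original point inherits the stage-2 label of its stage-1
  representative.

Restricting the expensive all-pairs path-distance computation to the reduced
representative set is also what makes the two-stage variant much faster than
the single-stage baselines, which pay for path distances over all points.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_array

from .core import Clustering, MedoidMap, MedoidShift
from .distances import KernelSpec

__all__ = [
    "TwoStageResult",
    "TwoStageMedoidShift",
    "cluster_no_kernel",
    "cluster_one_stage_kernel",
    "cluster_two_stage",
]

logger = logging.getLogger(__name__)


@dataclass
class TwoStageResult:
    """Everything the two-stage run produced, stage by stage."""

    stage1: MedoidMap
    representative_indices: np.ndarray
    stage2: Clustering
    final: Clustering
    config: dict = field(default_factory=dict)


class TwoStageMedoidShift(ClusterMixin, BaseEstimator):
    """Two-stage medoidshift clustering (denoise, then decompose).

    Parameters
    ----------
    h, c0 : float
        Bandwidth and density scale shared by both stages (defaults 1.0,
        assuming features normalised to [0, 1]).
    k_nn : int, default=10
        Neighbors per node for the stage-2 representative graph, clipped to
        ``n_representatives - 1``.
    exponent_sign : {"pos", "neg"}
        Sign convention of the stage-2 negative-exponential kernel.
    stage1_single_round : bool, default=True
        Run stage 1 as a single medoid-update round per point (the
        "denoised data after the first round" reading).  Iterating stage 1
        to a fixed point instead collapses the data to a handful of density
        modes, which discards the geometry stage 2 needs under noise.
    floor : float
        Kernel weight standing in for -inf at infinite path distance.

    Attributes
    ----------
    labels_ : ndarray of shape (m,) — final cluster label of every point.
    stage1_map_ : MedoidMap — stage-1 representative of every point.
    representative_indices_ : ndarray — unique stage-1 representatives
        (global data indices); the stage-2 input set.
    stage2_labels_ : ndarray — stage-2 label of each representative.
    medoid_indices_ : ndarray — global index of each final cluster medoid.
    cluster_centers_ : ndarray — coordinates of the final medoids.
    n_clusters_ : int
    """

    def __init__(
        self,
        h: float = 1.0,
        c0: float = 1.0,
        k_nn: int = 10,
        exponent_sign: str = "pos",
        stage1_single_round: bool = True,
        floor: float = -1e12,
    ) -> None:
        self.h = h
        self.c0 = c0
        self.k_nn = k_nn
        self.exponent_sign = exponent_sign
        self.stage1_single_round = stage1_single_round
        self.floor = floor

    def fit(self, X, y=None):
        X = check_array(X, ensure_min_samples=1)
        m = X.shape[0]

        stage1 = MedoidShift(
            kernel="flat",
            metric="sqeuclidean",
            h=self.h,
            c0=self.c0,
            single_round=self.stage1_single_round,
        ).fit(X)
        self.stage1_map_ = stage1.medoid_map_
        reps = np.unique(self.stage1_map_.rep)
        self.representative_indices_ = reps
        rep_pos = {int(r): i for i, r in enumerate(reps)}

        if len(reps) == 1:
            warnings.warn(
                "stage 1 collapsed to a single representative; result is one cluster",
                stacklevel=2,
            )
            self.stage2_labels_ = np.zeros(1, dtype=np.intp)
            self.labels_ = np.zeros(m, dtype=np.intp)
            self.medoid_indices_ = reps.copy()
        else:
            stage2 = MedoidShift(
                kernel="negexp",
                metric="path",
                h=self.h,
                c0=self.c0,
                k_nn=min(self.k_nn, len(reps) - 1),
                exponent_sign=self.exponent_sign,
                floor=self.floor,
            ).fit(X[reps])
            self.stage2_labels_ = stage2.labels_
            self.labels_ = np.array(
                [self.stage2_labels_[rep_pos[int(r)]] for r in self.stage1_map_.rep],
                dtype=np.intp,
            )
            self.medoid_indices_ = reps[stage2.medoid_indices_]
        self.cluster_centers_ = X[self.medoid_indices_]
        self.n_clusters_ = len(self.medoid_indices_)
        logger.info(
            "two-stage medoidshift: %d points -> %d representatives -> %d clusters",
            m, len(reps), self.n_clusters_,
        )
        return self

    def result_(self) -> TwoStageResult:
        """Bundle the fitted attributes into a :class:`TwoStageResult`."""
        final = Clustering(
            labels=self.labels_,
            representative_of_cluster={
                c: int(i) for c, i in enumerate(self.medoid_indices_)
            },
            n_clusters=self.n_clusters_,
        )
        stage2 = Clustering(
            labels=self.stage2_labels_,
            representative_of_cluster={
                c: int(i) for c, i in enumerate(self.medoid_indices_)
            },
            n_clusters=self.n_clusters_,
        )
        return TwoStageResult(
            stage1=self.stage1_map_,
            representative_indices=self.representative_indices_,
            stage2=stage2,
            final=final,
            config=self.get_params(),
        )


def _as_clustering(est: MedoidShift) -> Clustering:
    return Clustering(
        labels=est.labels_,
        representative_of_cluster={c: int(i) for c, i in enumerate(est.medoid_indices_)},
        n_clusters=est.n_clusters_,
    )


def cluster_no_kernel(
    X: np.ndarray, spec: KernelSpec | None = None, k_nn: int = 10
) -> Clustering:
    """Kernel-free baseline: flat weights on path distances over all points."""
    spec = spec or KernelSpec(mode="flat")
    est = MedoidShift(
        kernel="flat", metric="path", h=spec.h, c0=spec.c0, k_nn=k_nn
    ).fit(X)
    return _as_clustering(est)


def cluster_one_stage_kernel(
    X: np.ndarray, spec: KernelSpec | None = None, k_nn: int = 10
) -> Clustering:
    """Single-stage baseline: negative-exponential kernel on path distances."""
    spec = spec or KernelSpec(mode="negexp")
    est = MedoidShift(
        kernel="negexp",
        metric="path",
        h=spec.h,
        c0=spec.c0,
        k_nn=k_nn,
        exponent_sign=spec.exponent_sign,
        floor=spec.floor,
    ).fit(X)
    return _as_clustering(est)


def cluster_two_stage(
    X: np.ndarray,
    spec: KernelSpec | None = None,
    k_nn: int = 10,
    stage1_single_round: bool = True,
) -> TwoStageResult:
    """Run the proposed two-stage method and return the full per-stage result."""
    spec = spec or KernelSpec(mode="negexp")
    est = TwoStageMedoidShift(
        h=spec.h,
        c0=spec.c0,
        k_nn=k_nn,
        exponent_sign=spec.exponent_sign,
        stage1_single_round=stage1_single_round,
        floor=spec.floor,
    ).fit(X)
    return est.result_()
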