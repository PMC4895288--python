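"""Cluster-agreement scoring and the scenario x noise benchmark harness.

The adjusted Rand index (ARI) is the chance-corrected pair-counting
agreement between two partitions of the same points (Hubert–Arabie form):

    ARI = [ sum_ij C(n_ij,2) - E ] / [ (sum_i C(a_i,2) + sum_j C(b_j,2))/2 - E ],
    E   = sum_i C(a_i,2) * sum_j C(b_j,2) / C(n,2),

over the r x s contingency table n_ij of overlap counts with marginals a_i,
b_j.  ARI is 1 for identical partitions, ~0 for independent ones, and is
well suited here because the number of clusters is emergent and may differ
between truth and inference.
"""

from __future__ import annotations

import time
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import comb

from .simulate import generate_benchmark_replicate
from .twostage import cluster_no_kernel, cluster_one_stage_kernel, cluster_two_stage

__all__ = [
    "ContingencyTable",
    "contingency",
    "adjusted_rand_index",
    "ari",
    "BenchmarkSummary",
    "run_benchmark",
    "METHODS",
]


@dataclass
class ContingencyTable:
    """Overlap counts between two partitions, with marginals."""

    counts: np.ndarray
    row_labels: np.ndarray
    col_labels: np.ndarray

    @property
    def row_sums(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_sums(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def n(self) -> int:
        return int(self.counts.sum())


def contingency(truth, predicted) -> ContingencyTable:
    """Exact r x s overlap counts between the two labelings."""
    truth = np.asarray(truth)
    predicted = np.asarray(predicted)
    if truth.shape != predicted.shape or truth.ndim != 1 or len(truth) < 1:
        raise ValueError("labelings must be equal-length 1-d arrays of length >= 1")
    rows, ri = np.unique(truth, return_inverse=True)
    cols, ci = np.unique(predicted, return_inverse=True)
    counts = np.zeros((len(rows), len(cols)), dtype=np.int64)
    np.add.at(counts, (ri, ci), 1)
    return ContingencyTable(counts=counts, row_labels=rows, col_labels=cols)


def adjusted_rand_index(t: ContingencyTable) -> float:
    """Hubert–Arabie ARI of the contingency table; 1.0 when both partitions
    are trivial (degenerate zero-over-zero case)."""
    n = t.n
    if n < 2:
        raise ValueError("ARI needs at least 2 points")
    sum_cells = comb(t.counts, 2).sum()
    sum_a = comb(t.row_sums, 2).sum()
    sum_b = comb(t.col_sums, 2).sum()
    expected = sum_a * sum_b / comb(n, 2)
    max_index = 0.5 * (sum_a + sum_b)
    if max_index == expected:
        return 1.0
    return float((sum_cells - expected) / (max_index - expected))


def ari(truth, predicted) -> float:
    """Convenience: ARI directly from two label vectors."""
    return adjusted_rand_index(contingency(truth, predicted))


METHODS = {
    "nokernel": lambda X, k_nn: cluster_no_kernel(X, k_nn=k_nn).labels,
    "kernel": lambda X, k_nn: cluster_one_stage_kernel(X, k_nn=k_nn).labels,
    "twostage": lambda X, k_nn: cluster_two_stage(X, k_nn=k_nn).final.labels,
}


@dataclass
class BenchmarkSummary:
    """Tidy per-replicate benchmark records plus summary accessors."""

    records: pd.DataFrame  # scenario, sigma, method, replicate, ari, runtime_s, ...

    def summary(self) -> pd.DataFrame:
        """Mean/variance of ARI and mean runtime per (scenario, sigma, method)."""
        g = self.records.groupby(["scenario", "sigma", "method"])
        out = g.agg(
            mean_ari=("ari", "mean"),
            var_ari=("ari", "var"),
            mean_runtime_s=("runtime_s", "mean"),
            n_replicates=("ari", "size"),
        )
        return out.reset_index()


def run_benchmark(
    scenarios,
    sigmas,
    n_replicates: int,
    methods=("nokernel", "kernel", "twostage"),
    seed: int = 0,
    n_points: int = 500,
    p: int = 10,
    k_nn: int = 10,
) -> BenchmarkSummary:
    """Score each clustering variant on seeded replicates of each scenario.

    For every (scenario, sigma, replicate) cell one labeled cloud is
    generated and every method is run on that same cloud, so method
    comparisons are paired.  Replicate seeds are spawned deterministically
    from the master seed, making any single cell independently
    reproducible.  Per-replicate failures are recorded (ari = NaN) rather
    than aborting the sweep.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    from .simulate import SCENARIO_SUBSIMPLICES

    scenario_ids = {name: i for i, name in enumerate(SCENARIO_SUBSIMPLICES)}
    rows = []
    for scenario in scenarios:
        for sigma in sigmas:
            # cell seeds are keyed by (scenario, sigma), not list order, so
            # any single cell is reproducible in isolation
            cell_ss = np.random.SeedSequence(
                seed, spawn_key=(scenario_ids[scenario], int(round(sigma * 1000)))
            )
            rep_seeds = cell_ss.spawn(n_replicates)
            for r, rep_seed in enumerate(rep_seeds):
                X, truth, _ = generate_benchmark_replicate(
                    scenario, n_points=n_points, p=p, sigma=sigma, seed=rep_seed
                )
                for method in methods:
                    t0 = time.perf_counter()
                    try:
                        labels = METHODS[method](X, k_nn)
                        score = ari(truth, labels)
                        n_clusters = int(len(np.unique(labels)))
                        err = ""
                    except Exception as exc:  # recorded, not fatal
                        score, n_clusters, err = np.nan, 0, str(exc)
                    rows.append({
                        "scenario": scenario,
                        "sigma": sigma,
                        "method": method,
                        "replicate": r,
                        "ari": score,
                        "runtime_s": time.perf_counter() - t0,
                        "n_clusters": n_clusters,
                        "error": err,
                    })
    return BenchmarkSummary(records=pd.DataFrame(rows))
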