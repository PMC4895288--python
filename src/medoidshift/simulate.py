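"""Synthetic tumor-mixture clouds on simplicial complexes.

Each scenario encodes a small tumor phylogeny: cell types are basis vectors
in a p-dimensional (PCA-like) genomic space, and each root-to-leaf
progression path contributes a subsimplex — the set of tumors explainable as
mixtures of that path's cell types.  Two paths sharing early progression
states share basis vertices, so the subsimplices are glued along a shared
point, edge, or face, forming a simplicial complex.  A simulated bulk tumor
draws uniform mixture fractions over its subsimplex's cell types,

    y_j = sum_r f_r b_rj / sum_r f_r,      f_r ~ unif[0, 1],

placing the noiseless sample inside the convex hull of its subsimplex;
measurement error adds i.i.d. N(0, sigma) per dimension.  The ground-truth
label of a point is the subsimplex it was drawn from.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import normalize_unit_range

__all__ = [
    "SCENARIO_SUBSIMPLICES",
    "Scenario",
    "MixtureSample",
    "make_scenario",
    "sample_mixture",
    "add_noise",
    "generate_benchmark_replicate",
]

#: Subsimplex vertex-index sets (0-based) for the seven progression scenarios.
SCENARIO_SUBSIMPLICES: dict[str, tuple[tuple[int, ...], ...]] = {
    "tri_tri_edge": ((0, 1, 2), (1, 2, 3)),        # two triangles sharing an edge
    "tri_tri_point": ((0, 1, 2), (2, 3, 4)),       # two triangles sharing a point
    "tet_tet_point": ((0, 1, 2, 3), (3, 4, 5, 6)), # two tetrahedra sharing a point
    "tet_tet_edge": ((0, 1, 2, 3), (2, 3, 4, 5)),  # two tetrahedra sharing an edge
    "tet_tet_face": ((0, 1, 2, 3), (1, 2, 3, 4)),  # two tetrahedra sharing a face
    "tri_tet_edge": ((0, 1, 2), (1, 2, 3, 4)),     # triangle + tetrahedron, shared edge
    "tri_tet_point": ((0, 1, 2), (2, 3, 4, 5)),    # triangle + tetrahedron, shared point
}

#: Noise standard deviations swept in the benchmark.
NOISE_LEVELS = (0.0, 0.05, 0.1, 0.15, 0.2)


@dataclass
class Scenario:
    """A simplicial-complex mixture scenario with concrete basis vectors."""

    name: str
    basis: np.ndarray  # (k, p) cell-type genomic profiles
    subsimplices: tuple[tuple[int, ...], ...]

    @property
    def n_basis(self) -> int:
        return self.basis.shape[0]

    @property
    def p(self) -> int:
        return self.basis.shape[1]

    @property
    def shared(self) -> tuple[int, ...]:
        """Basis indices belonging to more than one subsimplex."""
        counts: dict[int, int] = {}
        for sub in self.subsimplices:
            for i in sub:
                counts[i] = counts.get(i, 0) + 1
        return tuple(sorted(i for i, c in counts.items() if c > 1))


@dataclass
class MixtureSample:
    """One simulated bulk tumor: fractions, clean and noisy profiles, label."""

    fractions: np.ndarray
    y: np.ndarray
    true_label: int
    x: np.ndarray | None = None


def _affinely_independent(vertices: np.ndarray, tol: float = 1e-8) -> bool:
    diffs = vertices[1:] - vertices[0]
    return np.linalg.matrix_rank(diffs, tol=tol) == len(vertices) - 1


def make_scenario(
    name: str,
    p: int = 10,
    seed: int | np.random.SeedSequence | None = 0,
    min_separation: float = 0.5,
    max_tries: int = 1000,
) -> Scenario:
    """Draw a concrete scenario: basis vectors uniform in [0, 1]^p.

    The basis is redrawn until every subsimplex has pairwise vertex
    distances of at least ``min_separation`` and full affine rank, giving
    nondegenerate, roughly unit-scale simplices (consistent with the h = 1
    bandwidth assumption).  Deterministic for a given seed.
    """
    if name not in SCENARIO_SUBSIMPLICES:
        raise ValueError(
            f"unknown scenario {name!r}; valid names: {sorted(SCENARIO_SUBSIMPLICES)}"
        )
    subs = SCENARIO_SUBSIMPLICES[name]
    k = max(max(s) for s in subs) + 1
    largest = max(len(s) for s in subs)
    if p < largest:
        raise ValueError(f"ambient dimension p={p} < largest subsimplex size {largest}")
    rng = np.random.default_rng(seed)
    for _ in range(max_tries):
        basis = rng.uniform(0.0, 1.0, size=(k, p))
        ok = True
        for sub in subs:
            V = basis[list(sub)]
            d = np.linalg.norm(V[:, None, :] - V[None, :, :], axis=-1)
            iu = np.triu_indices(len(sub), 1)
            if (d[iu] < min_separation).any() or not _affinely_independent(V):
                ok = False
                break
        if ok:
            return Scenario(name=name, basis=basis, subsimplices=subs)
    raise RuntimeError(
        f"could not draw a valid basis for {name!r} in {max_tries} tries"
    )


def sample_mixture(
    scenario: Scenario,
    n_points: int,
    seed: int | np.random.SeedSequence | None = 0,
    weights: np.ndarray | None = None,
) -> list[MixtureSample]:
    """Draw ``n_points`` noiseless mixture samples across the subsimplices.

    Points are split equally across subsimplices (remainder to the first)
    unless ``weights`` gives relative allocation weights, which models the
    uneven manifold sampling seen in real cohorts.  Per point, fractions are
    unif[0, 1] per vertex (redrawn in the measure-zero all-zero case) and
    the clean profile is the fraction-weighted affine combination of the
    subsimplex's basis vectors.
    """
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    rng = np.random.default_rng(seed)
    n_sub = len(scenario.subsimplices)
    if weights is None:
        counts = [n_points // n_sub] * n_sub
        counts[0] += n_points - sum(counts)
    else:
        w = np.asarray(weights, dtype=float)
        if len(w) != n_sub or (w < 0).any() or w.sum() == 0:
            raise ValueError("weights must be nonnegative, one per subsimplex")
        counts = np.floor(n_points * w / w.sum()).astype(int).tolist()
        counts[0] += n_points - sum(counts)
    samples: list[MixtureSample] = []
    for label, (sub, cnt) in enumerate(zip(scenario.subsimplices, counts)):
        B = scenario.basis[list(sub)]
        for _ in range(cnt):
            f = rng.uniform(0.0, 1.0, size=len(sub))
            while f.sum() == 0.0:
                f = rng.uniform(0.0, 1.0, size=len(sub))
            y = f @ B / f.sum()
            samples.append(MixtureSample(fractions=f, y=y, true_label=label))
    return samples


def add_noise(
    samples: list[MixtureSample],
    sigma: float,
    seed: int | np.random.SeedSequence | None = 0,
) -> list[MixtureSample]:
    """Attach noisy profiles x = y + N(0, sigma) i.i.d. per dimension.

    ``sigma=0`` copies the clean profile bitwise.  Returns new sample
    objects; the inputs are not modified.
    """
    if sigma < 0:
        raise ValueError("noise standard deviation must be >= 0")
    rng = np.random.default_rng(seed)
    out = []
    for s in samples:
        x = s.y.copy() if sigma == 0 else s.y + rng.normal(0.0, sigma, size=s.y.shape)
        out.append(MixtureSample(fractions=s.fractions, y=s.y, true_label=s.true_label, x=x))
    return out


def generate_benchmark_replicate(
    name: str,
    n_points: int = 500,
    p: int = 10,
    sigma: float = 0.0,
    seed: int | np.random.SeedSequence = 0,
    normalize: bool = True,
    weights: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, Scenario]:
    """One labeled benchmark replicate: scenario -> mixtures -> [0,1] -> noise.

    Returns the (n_points, p) observed matrix, the ground-truth subsimplex
    labels, and the scenario drawn.  The master seed is split into
    independent streams for the basis, the mixture fractions, and the noise.
    The *noiseless* cloud is min-max normalised to [0, 1] per dimension
    before noise is added, so that sigma is literally the noise standard
    deviation relative to a unit-range signal — the noise-to-signal reading
    of the sigma sweep, and the scale the h = 1 bandwidth assumes.
    (Normalising the observed, noisy matrix instead would compress the
    signal by the noise tails and silently change the meaning of sigma.)
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    s_basis, s_mix, s_noise = ss.spawn(3)
    scenario = make_scenario(name, p=p, seed=s_basis)
    samples = sample_mixture(scenario, n_points, seed=s_mix, weights=weights)
    if normalize:
        Y = np.vstack([s.y for s in samples])
        Yn = normalize_unit_range(Y)
        samples = [
            MixtureSample(fractions=s.fractions, y=yn, true_label=s.true_label)
            for s, yn in zip(samples, Yn)
        ]
    samples = add_noise(samples, sigma, seed=s_noise)
    X = np.vstack([s.x for s in samples])
    labels = np.array([s.true_label for s in samples], dtype=np.intp)
    return X, labels, scenario
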