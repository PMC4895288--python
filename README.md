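# medoidshift

Two-stage medoidshift clustering for decomposing tumor genomic point clouds
into low-dimensional subspaces.

## The problem

Bulk tumor genomic profiles (e.g. copy-number measurements) are mixtures of
the genomic profiles of the cell populations making up each tumor. If a
cohort's tumors evolve along a few shared progression pathways, each tumor
subtype mixes a particular *subset* of a common set of cell types, so its
samples occupy a low-dimensional simplex whose vertices are those cell-type
profiles. Subtypes sharing early progression states share vertices, and the
whole cohort forms a *simplicial complex* — triangles and tetrahedra glued
along shared points, edges, or faces. Recovering which tumors belong to
which subsimplex is a prerequisite for accurate mixture deconvolution, and
it is exactly the clustering problem ordinary methods (k-means,
hierarchical, Gaussian mixtures) are not built for: the clusters are not
spatially separated blobs but distinct low-dimensional pieces of one
contiguous point cloud.

## The method

Medoidshift is mode-seeking clustering in which each point iteratively moves
to the *data point* minimising a kernel-weighted sum of distances,

    y_{k+1} = argmin_y  Σ_i  D(x_i, y) · φ(‖(x_i − y_k)/h‖²),

so cluster representatives are always observed samples. This package runs it
in two stages:

1. **Denoise** — kernel-free (flat-profile) medoidshift on squared Euclidean
   distances in the ambient space. One update round maps every point to the
   medoid of its unit neighborhood; the distinct medoids are a reduced,
   denoised stand-in for the data.
2. **Decompose** — medoidshift with the negative-exponential kernel
   K = 1 − e^{D/h} on ISOMAP-style shortest-path distances (squared-Euclidean
   edge weights over a k-nearest-neighbor graph) built on the representatives
   only. Increasingly negative weights for distant points drive
   representatives to extreme points of distinct subspaces, splitting the
   complex into its subsimplices. Every sample inherits the label of its
   stage-1 representative.

Two single-stage baselines (flat or negative-exponential kernel on path
distances over all points) are included, along with the simplicial-complex
simulator (seven progression scenarios, uniform mixture fractions, Gaussian
ambient noise), an adjusted-Rand-index benchmark harness, and a SEG → block
matrix → PCA → [0,1] copy-number preprocessing chain.

## Worked example

```python
from medoidshift import TwoStageMedoidShift, generate_benchmark_replicate, ari

X, truth, scenario = generate_benchmark_replicate(
    "tri_tri_point", n_points=500, p=10, sigma=0.1, seed=0
)
model = TwoStageMedoidShift().fit(X)
print(f"points: {X.shape[0]}  stage-1 representatives: "
      f"{len(model.representative_indices_)}  clusters: {model.n_clusters_}")
print(f"cluster medoids (data indices): {model.medoid_indices_.tolist()}")
print(f"adjusted Rand index vs ground truth: {ari(truth, model.labels_):.3f}")
```

prints

```
points: 500  stage-1 representatives: 40  clusters: 2
cluster medoids (data indices): [82, 281]
adjusted Rand index vs ground truth: 0.968
```

Two triangles sharing a point, sampled at 500 tumors with 10% noise: stage 1
compresses the cloud to 40 representatives, stage 2 splits them into the two
subsimplices, and the inherited labels agree with the generating truth at
ARI 0.968 (1.0 would be perfect, ~0 is chance). The estimators follow
scikit-learn conventions (`fit`/`fit_predict`, `get_params`, trailing
underscore attributes) and compose with sklearn tooling.

The same workflow is available from the shell:

```sh
medoidshift simulate --scenario tri_tri_point --sigma 0.1 --seed 0 --out-dir out
medoidshift cluster out/tri_tri_point_sigma0.1_seed0.tsv --method twostage --out-dir out
medoidshift evaluate out/tri_tri_point_sigma0.1_seed0.tsv out/labels.tsv
```

plus `preprocess` (SEG copy-number calls → normalised principal-component
matrix), `benchmark` (scenario × noise × method ARI sweep) and `fixture`
(deterministic toy inputs).

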