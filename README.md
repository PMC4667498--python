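# lracluster

Integrative clustering of multi-omics data by convex low-rank
approximation.

Large cancer cohorts are profiled on several platforms at once — somatic
mutations (binary), copy number and DNA methylation (continuous), RNA-seq
counts — and a central question is whether the samples split into molecular
subtypes. `lracluster` finds one shared low-dimensional subspace across all
of these feature-by-sample matrices and clusters the samples in it. It is
aimed at analysts who have pre-matched matrices of different data types for
the same samples and want a fast, deterministic, convex alternative to
latent-factor models fitted by EM.

## Model

Each observed entry is a random variable conditional on a natural parameter
Θᵢⱼ, with the observation model chosen per matrix: X ~ N(Θ, 1) for
continuous data, X ~ Bernoulli(σ(Θ)) for binary data, X ~ Poisson(e^Θ) for
counts (categorical data enter via one-hot dummy coding). The stacked
parameter matrix Θ is assumed low-rank, giving the convex program

    min_Θ  L(Θ) + μ‖Θ‖*

with L the summed minus log-likelihood and ‖·‖* the nuclear norm. The fit
alternates gradient steps (δ = 0.5) with singular value shrinkage
D_μ(λ) = max(λ − μ, 0), where μ is re-chosen each iteration as the
(r+1)-th largest singular value, so the user tunes the target dimension r
directly instead of μ. The rank is picked at the elbow of the
explained-variation curve EV(r) = (ℒ*ᵣ − ℒ*₀)/(ℒ*∞ − ℒ*₀) ∈ [0, 1]; the
sample coordinates are the leading r components of ΣVᵀ; k-means with
silhouette-based selection of k proposes the subtypes. With only centered
continuous input the fitted subspace is exactly the PCA subspace.

See `docs/methods.md` for assumptions, numerical choices and limitations.

## Worked example

```python
import numpy as np
from sklearn.metrics import adjusted_rand_score
from lracluster import (
    SolverConfig, best_k, default_spec, fit, reduce,
    scan_clusters, scan_rank, simulate_dataset,
)
from lracluster.solver import elbow_rank

# planted-structure dataset: 90 samples, 3 clusters, rank 2,
# 200 gaussian + 100 binary + 150 poisson features
blocks, truth = simulate_dataset(default_spec(seed=7))

curve = scan_rank(blocks, [1, 2, 3, 4, 5])
for entry in curve:
    print(f"rank {entry.rank}: explained variation {entry.explained_variation:.4f}")
r = elbow_rank(curve)
print(f"elbow rank: {r}")

result = fit(blocks, SolverConfig(rank=r))
print(f"converged in {result.n_iter} iterations")

rep = reduce(result.theta, r)
kcurve = scan_clusters(rep, range(2, 7), seed=7)
for e in kcurve:
    print(f"k={e.k}: silhouette {e.silhouette:.3f}")
k = best_k(kcurve)
labels = next(e.result.labels for e in kcurve if e.k == k)
print(f"chosen k: {k}, ARI vs planted labels: "
      f"{adjusted_rand_score(truth['labels'], labels):.3f}")
```

Output:

```
rank 1: explained variation 0.0207
rank 2: explained variation 0.2221
rank 3: explained variation 0.2235
rank 4: explained variation 0.2261
rank 5: explained variation 0.2263
elbow rank: 2
converged in 27 iterations
k=2: silhouette 0.413
k=3: silhouette 0.553
k=4: silhouette 0.483
k=5: silhouette 0.448
k=6: silhouette 0.386
chosen k: 3, ARI vs planted labels: 0.868
```

Reading the numbers: explained variation jumps at rank 2 and flattens —
the elbow recovers the planted rank. The silhouette curve peaks at k = 3,
the planted cluster number. The adjusted Rand index of 0.87 against the
planted labels is essentially the Bayes ceiling at this separation
(the latent clusters overlap; see `docs/methods.md`), so the pipeline is
recovering all the structure the data contain.

## Command line

The same workflow is available as a CLI:

```sh
lracluster simulate --out data/ --seed 7
lracluster run data/gaussian0.tsv data/binary1.tsv data/poisson2.tsv \
    --dtype gaussian --dtype binary --dtype poisson \
    --rank-scan 1,2,3,4,5 --ks 2,3,4,5,6 --out results/
```

`run` writes the rank-scan and silhouette curves, per-iteration fit
diagnostics (objective, μ, explained variation), sample coordinates,
cluster labels, per-cluster signature tables, and a config/seed/versions
log sufficient to reproduce the run. Input matrices are feature-by-sample
TSV/CSV with header row and id column; `NA` cells are treated as missing.

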