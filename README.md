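# scirt

Iterative dropout imputation and dimensionality reduction for single-cell
RNA-seq expression matrices.

Single-cell RNA-seq suffers from *dropout*: failed mRNA capture records a
zero even when a gene is expressed, leaving the gene-by-cell matrix so
sparse that clustering and other downstream analyses degrade badly. This
package reimplements **scIRT**, a pipeline that estimates those missing
values while simultaneously producing a low-dimensional representation of
the cells that is often better for clustering than the imputed matrix
itself. It is aimed at computational biologists preparing scRNA-seq count
matrices for cell-type clustering and visualization.

## The method

Given a non-negative cells × genes matrix *A* with *y* cells and an
expected number of cell types *nc*:

1. **Ensemble cell similarity.** For each of several distance metrics
   (euclidean, 1−Pearson, 1−Spearman, cosine), compute the cell–cell
   distance matrix *DISⁿ*, convert every row to an ordinal ranking
   *Rⁿᵢ\* = rank(DISⁿᵢ\*)* with the cell itself at rank 1, and aggregate
   into a consensus *M = Σₙ tₙ Rⁿ* (all weights *tₙ = 1* by default).
   Working at the rank level makes metrics on different scales
   commensurable.

2. **SMOTE-style random imputation.** Each cell is updated as a convex
   blend *aᵢ\* = (1 − RE)·aᵢ + Σ_{j≠i} f_ij·aⱼ*, where the external
   weights *f_ij* sum exactly to *RE* (default 0.9). Raw weights follow
   the geometric pmf *P(X = x) = (1 − p)^{x−1} p* along the consensus
   similarity ranking, randomly shuffled among similarly ranked cells so
   the single nearest neighbor is not always dominant.

3. **Multi-layer schedule with a low-rank constraint.** The number of
   layers is *⌊log₂(y/nc)⌋*. Layer ℓ uses *p = 1/2^ℓ*, concentrating
   weight on the 2, 4, 8, … nearest cells; the top layer uses the flat
   *p = nc/y*, whose expectation is the average cluster size. After each
   layer the matrix is replaced by its rank-*k* NMF reconstruction
   (Lee–Seung multiplicative updates, Gaussian or Poisson noise model),
   which pulls the layer's result toward a *k*-type structure. A final
   factorization *A\* ≈ Z·H* yields the imputed **high-dimensional**
   matrix *Z·H* (cells × genes) and the **low-dimensional** representation
   *Z* (cells × k) used for clustering.

The package also ships a negative-binomial cluster simulator with an exact
dropout-masking protocol, and the evaluation metrics used throughout the
method's benchmarks (ARI, NMI, silhouette, Davies–Bouldin, flattened-matrix
Pearson `corr2`).

## Worked example

```python
import numpy as np
from scirt import (
    SimulationConfig, generate_clustered_counts, apply_dropout,
    run_scirt, ScirtConfig, kmeans_cluster, adjusted_rand_index,
)

# 300 cells x 500 genes, 3 cell types, then mask 60% of entries to zero
matrix, labels = generate_clustered_counts(SimulationConfig(seed=1))
masked, mask = apply_dropout(matrix, rate=0.6, seed=1)

result = run_scirt(masked, nc=3, config=ScirtConfig(seed=1))
truth = labels.as_codes()
for name, data in [("raw masked", masked.values),
                   ("scIRT low-dim", result.low_dim)]:
    ari = adjusted_rand_index(truth, kmeans_cluster(data, 3, seed=1).assignments)
    print(f"{name}: ARI = {ari:.3f}")
```

prints

```
raw masked: ARI = 0.009
scIRT low-dim: ARI = 0.434
```

i.e. k-means on the 60%-masked counts barely recovers the planted cell
types for this replicate (ARI near 0), while clustering the pipeline's
low-dimensional factor recovers much of the structure. `result.high_dim`
holds the imputed cells × genes matrix and `result.per_layer_rms` the RMS
residual of each layer's low-rank reconstruction.

The same is available from the shell:

```sh
scirt simulate --cells 300 --genes 500 --clusters 3 --dropout 0.6 --seed 1 --out-prefix sim
scirt impute --input sim.matrix.csv --orientation cells_by_genes --clusters 3 --seed 1 --out-prefix run
scirt evaluate --matrix run.lowdim.csv --truth sim.labels.txt --metrics ari,nmi,sc,dbi
```

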