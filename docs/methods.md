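# Methods

## Model and procedure

The pipeline treats dropout imputation as iterative matrix reconstruction.
A non-negative cells × genes matrix *A* (y cells, s genes) is repeatedly
smoothed toward its neighbors and projected onto a rank-*k* non-negative
subspace:

1. **Consensus similarity.** Cell–cell dissimilarity is computed under an
   ensemble of metrics — euclidean, 1−Pearson, 1−Spearman and cosine —
   each converted to a per-cell ordinal ranking (self = rank 1, ties broken
   by lower cell index) and summed with unit weights into a consensus
   matrix. Rank aggregation removes the scale differences between metrics;
   the consensus ordering is invariant to any monotone rescaling of a
   single metric.

2. **Geometric-weighted blending.** Every cell is replaced by
   `(1 − RE)·a_i + Σ_{j≠i} f_ij·a_j`. Raw external weights follow the
   geometric pmf `(1 − p)^{x−1} p` evaluated along the consensus ranking
   (nearest neighbor gets pmf(1)), are shuffled within blocks of `window`
   consecutive ranks, and are rescaled to sum exactly to `RE`. The blend
   row therefore always sums to 1: a constant matrix is a fixed point, and
   non-negativity is preserved for any `RE ∈ [0, 1]`.

3. **Layer schedule.** With `nc` expected cell types, the layer count is
   `mean_number = floor(log2(y/nc))` and layer ℓ (1-based) uses
   `p = 1/2^ℓ`, so its geometric law has expectation 2, 4, 8, … — the
   neighborhood grows geometrically until it spans a cluster. The expected
   (shrunk) cluster size is `eec = floor(y/nc · shrink)`; the top layer,
   and any layer whose neighborhood `2^ℓ` exceeds `eec`, uses the flat
   parameter `p = nc/y`, which weights a whole cluster's worth of
   neighbors near-uniformly.

4. **Per-layer low-rank constraint.** After each layer's blending the
   matrix is replaced by its rank-*k* NMF reconstruction and the RMS
   residual is logged; NMF's own monotone descent is the only optimization
   applied. A final factorization of the last reconstruction produces the
   outputs: high-dimensional `Z·H` and low-dimensional `Z`.

The consensus is recomputed from the current matrix at each layer
(`freeze_ranks=True` restores the fixed-ranking alternative), matching the
method's iterative narrative in which the cell-similarity structure
sharpens from layer to layer.

## Assumptions

- Cells of the same type are closer to each other than to other types
  under at least a plurality of the ensemble metrics; blending then mixes
  mostly within types.
- The number of cell types `nc` is supplied by the user; it sets the layer
  count, the flat top-layer parameter and (by default) the NMF rank.
  Nothing estimates it.
- Zeros are not classified into "true" and "dropout" zeros; every entry is
  smoothed. Methods that model the zero mixture explicitly are a different
  family.

## Parameters

| name | default | meaning |
| --- | --- | --- |
| `re` | 0.9 | total external weight mass per cell; 0 = identity, 1 = fully replaced |
| `shrink` | 0.9 | shrinkage on the average cluster size when computing `eec` |
| `window` | 4 | rank-block size for the weight shuffle; 1 = deterministic weights |
| `k` | `nc` | NMF rank for the per-layer constraint and final factorization |
| `metrics` | 4 listed above | distance ensemble; configurable |
| `noise_model` | gaussian | NMF objective: Frobenius (gaussian) or generalized KL (poisson) |
| `nmf_max_iter`, `nmf_tol` | 200, 1e-4 | NMF stopping rule (relative objective change) |
| `seed` | 0 | master seed; the run is bit-reproducible given it |

`re = 0.9` and `shrink = 0.9` are the method's published operating point;
they are distinct parameters that happen to share a value. The metric
ensemble itself is a design choice: the method calls for "multiple"
metrics without naming them, so four standard, complementary ones are the
default and the set is configurable. The `window` shuffle is our concrete
reading of "weights randomly selected among similarly ranked cells"; one
knob controls how local the shuffle is. The geometric pmf is evaluated at
similarity rank − 1, so the nearest neighbor receives pmf(1).

## Synthetic data

`generate_clustered_counts` draws negative-binomial counts
(`variance = μ + μ²/r`) with log-normally jittered gene means around
`base_mean`, and per-cluster DE gene sets whose means are multiplied by
`effect_size`. Defaults — 300 cells × 500 genes, 3 clusters,
`de_fraction = 0.2`, `effect_size = 8`, `base_mean = 1.0`, dispersion
`r = 0.5` — are chosen so the clean data is cleanly separable (log1p
k-means ARI ≈ 1) while heavy masking degrades raw clustering
substantially, the regime imputation methods are built for; `r = 0.5`
(variance ≈ μ + 2μ²) is typical overdispersion for filtered UMI data.

`apply_dropout` masks an exact count `round(rate·y·s)` of positions drawn
uniformly over **all** elements (already-zero entries may be drawn; their
masking is recorded but changes no value), making dropout-rate assertions
exact. A `nonzero_only` flag restricts the draw to nonzero entries.

What the simulator does **not** emulate: library-size variation between
cells, expression-dependent (MNAR) dropout, gene–gene correlation beyond
the cluster structure, batch effects. Tests passing on this fixture show
the pipeline recovers planted cluster structure under uniform masking;
they do not certify performance on real data with structured missingness.

## Numerical choices

- NMF initialization: seeded uniform(0,1) entries scaled by
  `sqrt(mean(A)/k)`, putting the initial reconstruction on the data's
  scale. All denominators carry an epsilon of 1e-12 and factors are
  floored at epsilon so multiplicative updates cannot die at zero. The
  paired (Z then H) update is monotone in its objective; the suite checks
  this across 100 random instances for both noise models.
- KL objective uses the `0·log 0 = 0` convention.
- An all-zero input short-circuits to zero factors.
- Correlation distances for constant cell vectors are undefined and set to
  the maximum dissimilarity 2 (with a warning); likewise cosine for
  all-zero cells.
- All rank ties break by lower cell index; HVG variance ties break by
  original gene order. Both choices exist purely for determinism.
- The blend product `W @ A` is clipped at 0 to absorb float undershoot.
- Variance for HVG selection is the unbiased sample variance of the values
  as read; no implicit log transform is applied anywhere (an explicit
  `log1p` ranking flag exists on `select_hvg`).

## Design choices that were genuinely open

- **Layer loop vs. pure weight-matrix chain.** The multi-layer framework
  can be read as a single chained product of blend matrices, or as a loop
  that interleaves an NMF projection after every blend. The interleaved
  loop is implemented, being the more specific of the two formulations;
  the final factorization consumes the last layer's *reconstruction*.
- **Low-dimensional output is the cell-side factor** `Z` (cells × k) —
  the only reading under which clustering cells on it makes sense.
- **NMF rank defaults to `nc`** for both the per-layer constraint and the
  final factorization; the method fixes no rank.
- **NMI normalization** defaults to the arithmetic mean of entropies
  (min/geometric/max variants are exposed), and k-means (10 restarts,
  seeded) is the default clusterer; the benchmarks name neither.

## Problem sizes used in the checks

The acceptance script and the heaviest test use 10 replicates of the
default simulator shape (300 × 500, 3 types) at 60% masking — about 15 s
of compute — which is the smallest configuration where the
raw/plain-NMF/pipeline comparison is stable across seeds. Unit and
property tests run on matrices of at most a few dozen cells.

## Known limitations

- Consensus construction is O(y²) per metric per layer in memory and
  time; the implementation is dense and aimed at the small-sample regime
  (hundreds of cells), not atlas-scale data.
- The imputed `high_dim` matrix is a rank-k reconstruction, so per-gene
  values are smoothed; `corr2` against the unmasked truth drops as the
  masking rate grows even when clustering recovers fully.
- NMF solutions are local optima; different seeds give different (all
  valid) factor pairs. Determinism is per master seed, not across seeds.
- With `y/nc < 2` no layering is possible and the pipeline refuses to run.
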