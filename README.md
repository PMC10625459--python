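# fusecyto

Cell-type identification for highly multiplexed *in situ* imaging cytometry
(IMC, MIBI-TOF, CODEX, seqFISH and kin) by **multiview fusion of similarity
metrics over self-organizing-map prototypes**, together with the evaluation
indices, cluster-number estimators, synthetic-data generator and benchmark
harness needed to study it.

## The problem

Segmented imaging-cytometry experiments yield a matrix `X` of `N` cells by
`M` protein markers. Cells must be grouped into types, but the technologies
carry technical artifacts — notably multiplicative intensity shifts across
images and tissue regions — that act *per cell*: every marker of a cell is
scaled by a common factor. A Euclidean distance between two cells is
sensitive to that factor; correlation-type similarities, which only compare
the *profile* of a marker vector, are invariant to it. Clustering quality
therefore depends strongly on the similarity metric, and no single metric
dominates.

## The method

For cells *i, j* with expressions `x_im`, the package implements two metric
classes:

- distance-based: Euclidean `sqrt(Σ_m (x_im − x_jm)²)`, Manhattan
  `Σ_m |x_im − x_jm|`, Maximum `max_m |x_im − x_jm|`;
- correlation-based: Pearson `r`, Spearman `ρ` (Pearson on within-cell
  ranks) and cosine similarity, each mapped to a distance by
  `d = sqrt(2(1 − r)) ∈ [0, 2]`.

The clustering pipeline is:

1. **SOM** — a batch self-organizing map quantizes the `N` cells into
   `P = s²` prototype vectors on an `s × s` grid, with `s` chosen from the
   number of covariance eigenvalues that exceed the Tracy–Widom null for
   the largest eigenvalue of a white Wishart matrix (tested sequentially).
2. **Multiview fusion** — the Pearson, Spearman, cosine and Euclidean
   distance matrices between prototypes ("views") are each scaled by their
   maximum off-diagonal entry and averaged with equal weights:
   `D_fused = Σ_i w_i D_i`.
3. **Hierarchical clustering** — average-linkage (UPGMA) agglomeration of
   the fused prototype dissimilarity, cut at the requested `k`; cell labels
   are inherited from each cell's best-matching unit.

Also included: the four external indices (ARI, NMI, Fowlkes–Mallows,
pairwise F-measure) built from one pair-counting confusion vocabulary; six
cluster-number estimators (Gap, Silhouette, Jump, Slope, within-cluster
distance, and a Discriminant method combining discriminant projections with
Hartigan's dip test under Holm FWER control — the dip statistic is computed
exactly from its min-sup-distance definition); a Gaussian-mixture simulator
with per-cell lognormal scaling artifacts; and fixed-size / stratified
resampling benchmark harnesses.

## Worked example

```python
import numpy as np
from fusecyto import (
    SimulationSpec, simulate_cytometry, fusesom_cluster, RunConfig,
    Partition, score_all, estimate_k,
)

spec = SimulationSpec(n_cells=2000, n_markers=16, n_types=5,
                      mean_separation=8.0, seed=7)
data = simulate_cytometry(spec)
result = fusesom_cluster(data, k=5, config=RunConfig(seed=7))
truth = Partition(labels=np.asarray(data.annotations, dtype=object))
print("grid:", result.grid_side, "prototypes:", result.som.prototypes.shape[0])
for name, value in score_all(result.partition, truth).items():
    print(f"{name}: {value:.3f}")
for m in ("silhouette", "discriminant", "wcd"):
    est = estimate_k(result.som.prototypes, m, k_range=range(2, 11), seed=7)
    print(m, "k_hat:", est.k_hat)
```

prints

```
grid: 5 prototypes: 25
ARI: 1.000
NMI: 1.000
FM: 1.000
F: 1.000
silhouette k_hat: 6
discriminant k_hat: 4
wcd k_hat: 3
```

The eigenvalue test finds the five planted populations' worth of structure
and sizes a 5 × 5 grid; the fused pipeline recovers the planted labels
perfectly at the true `k` (all four indices equal 1). The estimators
bracket the planted `k = 5` from a 25-prototype summary rather than hitting
it exactly — choosing `k` is genuinely harder than clustering at a known
`k`, the estimators disagree by design (they formalize different notions of
cluster structure), and they are best read as an ensemble. Their accuracy
on adequately sized inputs is quantified by the acceptance script below.

The same pipeline is scriptable from the shell:

```sh
fusecyto simulate --out sim.csv --truth truth.csv --n 2000 --markers 16 --types 5 --seed 7
fusecyto cluster --input sim.csv --k 5 --seed 7 --out labels.csv
fusecyto estimate-k --input sim.csv --method discriminant
fusecyto evaluate --pred labels.csv --truth truth.csv
```

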