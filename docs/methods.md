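# Methods

This note records the models, numerical choices and known limitations
behind `fusecyto`, in the spirit of a statistical software appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Similarity metrics

Six pairwise dissimilarities over cells (or prototypes) are provided.
Distance-class metrics (Euclidean, Manhattan, Maximum/Chebyshev) act on raw
intensities and satisfy the metric axioms. Correlation-class metrics map a
similarity `r` — Pearson, Spearman (Pearson on within-row average ranks),
or cosine — to a distance `d = sqrt(2(1 − r))`. The square root matters:
it gives the codomain `[0, 2]`, makes `d` equal to the Euclidean distance
between z-scored rows divided by `sqrt(M)` (an identity the tests verify),
and makes `d` a proper metric on the profile sphere. Pearson distance is
invariant to per-cell affine maps `x → a x + b` (a > 0), cosine to positive
scaling, Spearman to any strictly increasing per-cell transform.

Degenerate rows: a constant row has no defined Pearson/Spearman
correlation and an all-zero row no cosine; both raise errors naming the
offending cell rather than silently producing NaNs, forcing the caller to
filter degenerate cells. A constant *nonzero* row is accepted by cosine,
which is well defined there — the error policy is per-metric, not blanket.

## SOM and grid sizing

The batch SOM uses a rectangular grid, linear (PCA-spanned) initialization
with a seeded jitter of relative size 1e-4, a Gaussian neighborhood on grid
coordinates whose radius decays linearly from `max(side)/2` to 0.5, and 10
epochs by default. Batch updates (prototype := kernel-weighted mean of all
cells) make the fit deterministic given the seed; prototypes receiving no
kernel mass keep their previous value. Best-matching units break ties
toward the lower prototype index.

Grid side: the number of "real" structure axes is estimated as the count
of covariance eigenvalues significantly exceeding the white-noise null.
The largest eigenvalue of an `n × p` white Wishart, Johnstone-standardized
with the half-corrected constants
`mu = (sqrt(n − 1/2) + sqrt(p − 1/2))²`,
`sigma = (sqrt(n − 1/2) + sqrt(p − 1/2)) (1/sqrt(n − 1/2) + 1/sqrt(p − 1/2))^{1/3}`,
follows the Tracy–Widom TW1 law; critical values 0.9793 / 2.0234 / 3.2724
at alpha = 0.05 / 0.01 / 0.001. Eigenvalues are tested largest-first; at
each step the remaining spectrum is rescaled to unit mean (scale
invariance) and the effective dimension shrinks by one. The side is
`max(5, ceil(sqrt(5 · k_sig)))` — five prototypes per significant
component, floored at a 5 × 5 grid; both constants are arguments.

A deliberate choice: the test operates on the column-*centered* (not
variance-standardized) covariance. Standardizing every column pins the
spectrum's trace exactly, which measurably deflates the largest
eigenvalue's fluctuation at moderate `M` and destroys the TW calibration
(empirical null exceedance ~0.007 instead of 0.05 at N = 2000, M = 20);
centering-only with the constants above is calibrated (~0.04, inside the
binomial band the acceptance test checks). Markers on wildly different
scales should be normalized upstream — consistent with the package
applying no internal intensity transforms whatsoever, because public
imaging datasets are distributed already preprocessed by their source
studies and re-normalizing would change the object under study.

## Fusion

Views (distance matrices over the same prototypes) live on incomparable
scales, so each is divided by its maximum off-diagonal entry before the
weighted sum; weights are normalized to sum to one and default to equal.
The fused matrix is therefore an entrywise convex combination of
max-scaled views: idempotent on duplicated views, permutation-equivariant,
and bounded by the min/max of the normalized views. Max-scaling before
summation is a design decision (the alternative — summing raw views —
would let the largest-scale view dominate silently).

## Hierarchical clustering

Average linkage (UPGMA) on the fused prototype dissimilarity, implemented
via `scipy.cluster.hierarchy`; merge heights are verified against a naive
O(P³) matrix-shrinking implementation in the tests, and average linkage is
monotone so dendrogram heights never invert. Tie-breaking among exactly
equal candidate merges follows scipy's deterministic nearest-neighbor-chain
order; exact ties have measure zero for continuous data, and all
reproducibility guarantees are stated for a fixed platform. Cutting to `k`
relabels clusters contiguously (1..k, order of first appearance);
back-projection to cells drops prototype clusters that own no cells,
re-compacts labels, and warns.

## Evaluation indices

ARI, NMI, Fowlkes–Mallows and the pairwise F-measure are all computed from
one contingency table / pair-confusion vocabulary (TP, FP, FN, TN over
unordered item pairs). The F-measure is the *pairwise* harmonic mean of
precision and recall — not the per-class best-match variant — so
`F ≤ FM` always (harmonic vs geometric mean), a property the tests assert
universally. NMI uses natural-log entropies with the arithmetic-mean
normalization `2 I / (H_x + H_y)`. Degenerate conventions: an ARI
denominator of zero returns 1 when the partitions are identical as set
partitions and 0 otherwise; NMI of two single-cluster partitions is 1;
FM/F with no within-cluster pairs in either partition is an error.
Orientation convention: first argument prediction, second truth (only F is
sensitive to it).

## Dip statistic and p-values

Hartigan's dip `D(F_n) = min_G sup_x |F_n(x) − G(x)|` over unimodal CDFs
`G` is computed exactly from the definition rather than by porting the
classical iterative code. The key observations:

- The mode may always be placed as an atom at one of the data values
  (a continuous mode is the zero-jump special case; a mode outside the
  data range is dominated by an atom at the nearest extreme).
- For a fixed mode atom, the left problem — a convex increasing
  sub-distribution fitting the ECDF within sup-distance `d` — is feasible
  iff `2d` exceeds the maximal gap between the ECDF's upper staircase
  corners and the greatest convex minorant of its lower corners; the right
  (concave) problem is its mirror image. Both profiles are computed for
  all mode positions in one amortized hull pass each.
- The two one-sided fits couple only through monotonicity at the mode
  (left limit ≤ CDF value there, with convexity propagating "forced
  slopes" between tubes). The coupling gap is piecewise linear and
  strictly decreasing in `d`; its root is found by bisecting the sorted
  admissibility thresholds and then Illinois false position, to ~1e-14.

The implementation agrees with an independent linear-programming oracle
(explicit piecewise-linear unimodal CDFs per mode placement) to better
than 1e-10 on hundreds of random samples with and without ties, and
reproduces the two-point-mass value of exactly 0.25.

`dip_test` draws its p-value from seeded Monte Carlo against uniform
samples of the same size (default 2000 replicates): the uniform is the
classical least-favorable unimodal null. The Discriminant estimator
instead uses lazily built, cached null tables on a logarithmic grid of
sample sizes, interpolating `sqrt(n)`-scaled dips between grid points
(the device used by published dip quantile tables), with a
peaks-over-threshold exponential extension of the top-decile tail so that
overwhelmingly bimodal projections can earn p-values below the empirical
floor `1/(B+1)` — without this, step-down FWER control over many
dendrogram nodes could never reject anything.

## Cluster-number estimators

All six estimators take their per-`k` partitions from cutting one
average-linkage tree — the same clustering path as the final solution —
rather than re-running a flat clusterer per `k`. Gap uses `B = 50` uniform
reference sets over each feature's observed range and the one-standard-
error rule; Jump uses distortion `d_k = W_k/(PM)` with transformation
power `Y = M/2` and `d_0^{-Y} = 0`; Slope is `−(s(k+1) − s(k)) s(k)^v`
with `v = 1` on the mean-silhouette curve; WCD takes the elbow (maximal
discrete second difference) of the mean within-cluster distance curve;
Silhouette the argmax of the mean silhouette width.

The Discriminant method builds the average-linkage tree, and for every
internal node with at least `min_node_size = 10` points (each child ≥ 2)
projects the node's points onto the two-class discriminant direction
`w ∝ S_w^{-1}(mu_1 − mu_2)` (ridge-regularized by a trace-scaled identity)
and dip-tests the projections — subsampled to at most 200 points at huge
nodes, which leaves the test exact under exchangeability while bounding
node cost. Node p-values are Holm-adjusted (valid under arbitrary
dependence; Bonferroni available) and the estimate is the number of
significant splits plus one.

Operating regime, measured on the separated-blob suite the acceptance
script reruns: distortion-based estimators are asymptotic in the number of
points per group and need a few dozen points per group — below roughly 40
points per group the Jump statistic systematically overshoots for small
true `k`, because post-true splits shrink the distortion faster than the
transformation assumes. The suite therefore uses 60 points per planted
group. Two further honest caveats: (i) run directly on SOM prototypes of
*very* tight clusters, WSS-based estimators can over-split, because
prototypes quantize each cluster into a regular lattice whose subdivision
keeps reducing WSS — estimates from a prototype summary should be read as
an ensemble across estimators; (ii) in higher dimensions the Discriminant
method tends to overestimate, since the children of a within-cluster node
were *selected* by the linkage to be separated, and the discriminant
projection of a few dozen points in many dimensions can make that
selection look bimodal. Both behaviors mirror the over/under-estimation
spread that motivates offering six estimators side by side.

## Synthetic data

`simulate_cytometry` draws per-type archetype mean vectors uniformly
(rejection-sampled until all pairwise distances reach
`mean_separation × noise_sd`; 1000 attempts before erroring), samples
cells from isotropic Gaussians around their archetype, multiplies each
cell by `exp(Normal(0, cell_scaling_sdlog))`, applies optional elementwise
dropout, and clamps at zero. The per-cell multiplicative factor is the
minimal formalization of cross-image intensity shifts: it leaves
correlation-class distances between cells exactly invariant while moving
Euclidean distances, which the tests assert directly.

What the generator does *not* emulate: spatial coordinates and
neighborhood effects, lateral marker spillover, marker–marker covariance
within a type (within-type noise is isotropic), and realistic count-like
intensity distributions. Passing tests on this generator therefore
demonstrate the pipeline's mechanics and its robustness to per-cell
scaling — not performance on any real tissue panel.

A consequence worth knowing: under `cell_scaling_sdlog = 0.4` the
Euclidean average-linkage baseline does not merely degrade — it collapses
(ARI near 0), because the scaling turns the brightest cells into distance
outliers that average linkage peels off as singletons. The measured
correlation-versus-Euclidean gap on this generator is therefore much
larger than gaps typically reported on real, pre-normalized datasets;
the comparison is directional, not a magnitude claim.

## Benchmark harness

Fixed-size subsampling draws `n_repeats` without-replacement subsets
(default five), stratified splitting takes `ceil(fraction · n_c)` cells of
every annotated class (default fraction 0.5), and each replicate is
clustered at its own annotated class count. Per-repeat RNG streams derive
deterministically from the master seed and repeat index, so any single
record is reproducible in isolation. The metric-combination sweep fits the
SOM once per dataset and varies only the view subset (all 15 nonempty
subsets of the four default views), so score differences isolate the view
set. Third-party clusterers enter only through the
`(data, k, seed) → Partition` adapter; none are bundled.

## Problem sizes

Defaults and test sizes were chosen as the smallest that keep each
statistic in its operating regime: N = 5000 cells / M = 20 markers / 8
types for end-to-end recovery, N = 800 / M = 12 / 4 types for the
artifact experiments, 60 points per group for the estimator suite,
N = 2000 / M = 20 / 200 replicates for the null-calibration check, and
B = 1000 for dip null tables (B = 50 for Gap references). The whole test
suite and the acceptance script each run in minutes on one CPU.
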