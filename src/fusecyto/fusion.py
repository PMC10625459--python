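"""Multiview integration of prototype-level distance matrices.

Each similarity metric yields one "view" of the prototypes — a full
dissimilarity matrix. Views live on incomparable scales (a Manhattan
distance versus a correlation distance bounded by 2), so each view is first
range-normalized by its own maximum off-diagonal entry and the fused matrix
is then the weighted sum with weights normalized to sum to one. With the
default equal weights the fused dissimilarity is simply the mean of the
max-scaled views, an entrywise convex combination.

The canonical view set is (pearson, spearman, cosine, euclidean), the
combination that performed best in the metric-combination study this
package reproduces on synthetic data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .metrics import DistanceMatrix, pairwise_distance

DEFAULT_VIEW_METRICS = ("pearson", "spearman", "cosine", "euclidean")


@dataclass
class FusedDistance:
    """Weighted sum of max-scaled views; symmetric, zero diagonal."""

    values: np.ndarray
    views: list[tuple[str, float]]
    normalization: str = "max-scaled"

    @property
    def n(self) -> int:
        return self.values.shape[0]


def fuse_distances(
    views: list[DistanceMatrix], weights: list[float] | None = None
) -> FusedDistance:
    """Fuse >= 1 distance matrices into one dissimilarity.

    Every view is divided by its maximum off-diagonal entry, then summed with
    the (sum-normalized) weights. All views must share dimension and item
    ordering; a view whose off-diagonal is identically zero is degenerate.
    """
    if not views:
        raise ValueError("need at least one view")
    n = views[0].values.shape[0]
    for v in views:
        if v.values.shape != (n, n):
            raise ValueError("all views must have identical dimensions")
    if weights is None:
        weights = [1.0] * len(views)
    if len(weights) != len(views):
        raise ValueError("weights length must match number of views")
    weights = np.asarray(weights, dtype=float)
    if np.any(weights <= 0):
        raise ValueError("weights must be positive")
    weights = weights / weights.sum()

    fused = np.zeros((n, n))
    tagged: list[tuple[str, float]] = []
    for v, w in zip(views, weights):
        vmax = float(v.values.max())
        if vmax <= 0:
            raise ValueError(
                f"view {v.metric!r} has an all-zero off-diagonal; cannot normalize"
            )
        fused += w * (v.values / vmax)
        tagged.append((v.metric, float(w)))
    fused = (fused + fused.T) / 2.0  # enforce exact symmetry
    np.fill_diagonal(fused, 0.0)
    return FusedDistance(values=fused, views=tagged)


def default_view_set(
    prototypes: np.ndarray, metrics: tuple[str, ...] = DEFAULT_VIEW_METRICS
) -> list[DistanceMatrix]:
    """Distance matrices over the prototypes for the canonical metric set, in order."""
    prototypes = np.asarray(prototypes, dtype=float)
    if prototypes.shape[0] < 3:
        raise ValueError("need at least 3 prototypes")
    return [pairwise_distance(prototypes, m) for m in metrics]
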