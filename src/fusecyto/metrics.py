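"""Pairwise cell–cell dissimilarities used throughout the pipeline.

Two families of metrics are supported. Distance-based metrics operate on raw
marker intensities:

* ``euclidean``  – sqrt(sum_m (x_im - x_jm)^2)
* ``manhattan``  – sum_m |x_im - x_jm|
* ``maximum``    – max_m |x_im - x_jm|  (Chebyshev)

Correlation-based metrics compare the *profile* of a cell's marker vector and
are converted to distances with ``sqrt(2 * (1 - r))`` where ``r`` is the
Pearson correlation, Spearman rank correlation, or cosine similarity between
the two rows. The square-root form maps r = 1 -> 0, r = 0 -> sqrt(2),
r = -1 -> 2, and coincides with the Euclidean distance between z-scored rows
divided by sqrt(M).

Correlation-based metrics are invariant to per-cell affine (Pearson),
monotone (Spearman), or positive-scale (cosine) transforms of the marker
vector, which is what makes them robust to per-cell multiplicative intensity
artifacts; the distance-based metrics are not.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import squareform, pdist
from scipy.stats import rankdata

DISTANCE_METRICS = ("euclidean", "manhattan", "maximum")
CORRELATION_METRICS = ("pearson", "spearman", "cosine")
ALL_METRICS = DISTANCE_METRICS + CORRELATION_METRICS

_BOUND_TOL = 1e-12


class MetricError(ValueError):
    """Unknown metric name or degenerate input for the requested metric."""


@dataclass
class DistanceMatrix:
    """Symmetric dissimilarity matrix tagged with the metric that produced it.

    ``values`` is an N x N symmetric matrix with zero diagonal and
    nonnegative entries; ``item_ids`` names the rows/columns.
    """

    values: np.ndarray
    metric: str
    item_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise ValueError("distance matrix must be square")
        if not self.item_ids:
            self.item_ids = [str(i) for i in range(n)]
        if len(self.item_ids) != n:
            raise ValueError("item_ids length must match matrix size")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)


def correlation_to_distance(r):
    """Map a correlation or cosine similarity in [-1, 1] to a distance in [0, 2].

    Uses d = sqrt(2 * (1 - r)), monotone decreasing in r. Values within
    1e-12 of the bounds are clamped; anything further out is rejected.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < -1.0 - _BOUND_TOL) or np.any(r > 1.0 + _BOUND_TOL):
        raise MetricError("correlation values must lie in [-1, 1]")
    r = np.clip(r, -1.0, 1.0)
    out = np.sqrt(2.0 * (1.0 - r))
    return out if out.ndim else float(out)


def rank_transform(data: np.ndarray) -> np.ndarray:
    """Replace each row by the ranks of its entries (ties get average ranks)."""
    data = np.asarray(data, dtype=float)
    if np.isnan(data).any():
        raise MetricError("rank_transform requires complete data")
    return rankdata(data, axis=1, method="average")


def _check_rows_for_correlation(data: np.ndarray, metric: str) -> None:
    if data.shape[1] < 2:
        raise MetricError(f"{metric} distance needs at least 2 markers")
    if metric in ("pearson", "spearman"):
        bad = np.where(np.ptp(data, axis=1) == 0)[0]
        if bad.size:
            raise MetricError(
                f"row {bad[0]} is constant across markers; {metric} correlation "
                "is undefined — filter degenerate cells first"
            )
    elif metric == "cosine":
        bad = np.where(~np.any(data != 0, axis=1))[0]
        if bad.size:
            raise MetricError(
                f"row {bad[0]} is all-zero; cosine similarity is undefined"
            )


def pairwise_distance(data, metric: str, item_ids=None) -> DistanceMatrix:
    """Compute the N x N dissimilarity matrix between rows of ``data``.

    ``metric`` is one of ``euclidean``, ``manhattan``, ``maximum``,
    ``pearson``, ``spearman``, ``cosine``. Correlation-class entries are
    ``sqrt(2 * (1 - r))``.
    """
    values = np.asarray(getattr(data, "values", data), dtype=float)
    if values.ndim != 2:
        raise MetricError("expected a 2-D cell-by-marker matrix")
    if item_ids is None:
        item_ids = list(getattr(data, "cell_ids", []) or [])

    if metric == "euclidean":
        d = pdist(values, metric="euclidean")
    elif metric == "manhattan":
        d = pdist(values, metric="cityblock")
    elif metric == "maximum":
        d = pdist(values, metric="chebyshev")
    elif metric in CORRELATION_METRICS:
        _check_rows_for_correlation(values, metric)
        if metric == "spearman":
            values = rank_transform(values)
        if metric == "cosine":
            r = 1.0 - pdist(values, metric="cosine")
        else:
            r = 1.0 - pdist(values, metric="correlation")
        d = correlation_to_distance(np.clip(r, -1.0, 1.0))
    else:
        raise MetricError(
            f"unknown metric {metric!r}; choose from {sorted(ALL_METRICS)}"
        )
    return DistanceMatrix(values=squareform(d), metric=metric, item_ids=item_ids)
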