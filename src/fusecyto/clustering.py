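"""Average-linkage clustering of prototypes and end-to-end orchestration.

The full pipeline is: (i) estimate a square SOM grid from the significant
eigenvalues of the marker covariance (unless a side is given), and train a
batch SOM; (ii) compute the configured similarity views between prototypes
and fuse them into a single dissimilarity; (iii) cluster the prototypes with
average-linkage (UPGMA) agglomerative clustering, cut the dendrogram at the
requested k, and project cluster labels back to cells through their
best-matching units. All randomness flows from one seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import cut_tree, linkage

from .evaluation import Partition
from .fusion import FusedDistance, default_view_set, fuse_distances
from .io_config import RunConfig
from .metrics import DistanceMatrix
from .som import SOMGrid, SOMModel, estimate_grid_side, fit_som


@dataclass
class Dendrogram:
    """Agglomerative merge tree over P leaves.

    ``merges`` is the scipy linkage matrix: P-1 rows (left, right, height,
    size), with cluster ids < P denoting leaves. Average linkage is monotone,
    so heights are nondecreasing.
    """

    merges: np.ndarray
    leaf_ids: list[str]

    @property
    def n_leaves(self) -> int:
        return self.merges.shape[0] + 1

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]


def hierarchical_average(d: DistanceMatrix | FusedDistance) -> Dendrogram:
    """Agglomerative UPGMA clustering of a symmetric dissimilarity matrix."""
    values = np.asarray(d.values, dtype=float)
    if values.shape[0] < 2:
        raise ValueError("need at least 2 items to cluster")
    if not np.allclose(values, values.T, atol=1e-8):
        raise ValueError("input dissimilarity matrix is not symmetric")
    n = values.shape[0]
    condensed = values[np.triu_indices(n, k=1)]
    z = linkage(condensed, method="average")
    leaf_ids = list(getattr(d, "item_ids", []) or [str(i) for i in range(n)])
    return Dendrogram(merges=z, leaf_ids=leaf_ids)


def cut_to_k(tree: Dendrogram, k: int, method: str = "average-linkage") -> Partition:
    """Cut the dendrogram into k clusters by removing the k-1 highest merges.

    Labels are contiguous 1..k in order of first appearance; no cluster is
    empty.
    """
    p = tree.n_leaves
    if not 1 <= k <= p:
        raise ValueError(f"k must be in [1, {p}]; got {k}")
    raw = cut_tree(tree.merges, n_clusters=k).ravel()
    labels = _compact_labels(raw)
    return Partition(labels=labels, method=method, k=k)


def _compact_labels(raw: np.ndarray) -> np.ndarray:
    """Relabel to contiguous 1..k in order of first appearance."""
    _, first = np.unique(raw, return_index=True)
    order = raw[np.sort(first)]
    mapping = {lab: i + 1 for i, lab in enumerate(order)}
    return np.asarray([mapping[v] for v in raw], dtype=int)


def project_labels(proto_partition: Partition, bmu: np.ndarray) -> Partition:
    """Give every cell the cluster label of its best-matching prototype.

    Prototype clusters that receive no cells are dropped and the remaining
    labels re-compacted (with a warning), so cell labels are contiguous.
    """
    bmu = np.asarray(bmu)
    p = len(proto_partition)
    if bmu.min() < 0 or bmu.max() >= p:
        raise ValueError("bmu indices out of range")
    cell_raw = proto_partition.labels[bmu]
    if len(np.unique(cell_raw)) < proto_partition.k:
        warnings.warn(
            "some prototype clusters received no cells; labels re-compacted",
            stacklevel=2,
        )
    labels = _compact_labels(cell_raw)
    return Partition(
        labels=labels,
        method=proto_partition.method,
        k=int(labels.max()),
        seed=proto_partition.seed,
    )


@dataclass
class ClusteringResult:
    """Cell partition plus every intermediate for audit and reuse."""

    partition: Partition
    som: SOMModel
    views: list[DistanceMatrix]
    fused: FusedDistance
    tree: Dendrogram
    grid_side: int


def fusesom_cluster(
    data,
    k: int,
    config: RunConfig | None = None,
    som_model: SOMModel | None = None,
) -> ClusteringResult:
    """Run the full prototype-fusion clustering pipeline at a given k.

    ``som_model`` lets callers (the metric-combination sweep, estimators)
    reuse one trained SOM across several view sets. Deterministic given
    ``config.seed``.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    config = config or RunConfig()
    x = np.asarray(getattr(data, "values", data), dtype=float)
    if x.shape[0] < 10:
        raise ValueError("need at least 10 cells")

    if som_model is None:
        side = config.grid_side or estimate_grid_side(
            x, alpha=config.alpha, min_side=config.min_grid_side
        )
        side = min(side, int(np.sqrt(x.shape[0])))  # never more prototypes than cells
        som_model = fit_som(
            x, SOMGrid(side), epochs=config.som_epochs, seed=config.seed
        )
    views = default_view_set(som_model.prototypes, tuple(config.metric_set))
    fused = fuse_distances(views)
    tree = hierarchical_average(fused)
    proto_part = cut_to_k(tree, k, method="fusesom")
    proto_part.seed = config.seed
    partition = project_labels(proto_part, som_model.bmu)
    return ClusteringResult(
        partition=partition,
        som=som_model,
        views=views,
        fused=fused,
        tree=tree,
        grid_side=som_model.grid.side_x,
    )
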