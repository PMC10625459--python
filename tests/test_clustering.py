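import numpy as np
import pytest

from fusecyto.clustering import (
    cut_to_k,
    fusesom_cluster,
    hierarchical_average,
    project_labels,
)
from fusecyto.evaluation import Partition, adjusted_rand_index
from fusecyto.io_config import RunConfig
from fusecyto.metrics import DistanceMatrix, pairwise_distance
from oracles import naive_upgma_heights


def test_upgma_hand_case_four_points_on_a_line():
    pts = np.array([[0.0], [1.0], [10.0], [11.0]])
    tree = hierarchical_average(pairwise_distance(pts, "euclidean"))
    heights = np.sort(tree.heights)
    assert heights[0] == pytest.approx(1.0)
    assert heights[1] == pytest.approx(1.0)
    assert heights[2] == pytest.approx(10.0)  # mean of 9,10,10,11
    part = cut_to_k(tree, 2)
    assert part.labels[0] == part.labels[1]
    assert part.labels[2] == part.labels[3]
    assert part.labels[0] != part.labels[2]


def test_two_items_merge_at_their_distance():
    d = DistanceMatrix(values=np.array([[0.0, 3.5], [3.5, 0.0]]), metric="euclidean")
    tree = hierarchical_average(d)
    assert tree.heights[0] == pytest.approx(3.5)


def test_upgma_merge_heights_match_cubic_oracle(rng):
    for _ in range(10):
        p = int(rng.integers(20, 51))
        m = rng.uniform(0.5, 10, size=(p, p))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        d = DistanceMatrix(values=m, metric="euclidean")
        got = np.sort(hierarchical_average(d).heights)
        want = np.sort(naive_upgma_heights(m))
        assert np.allclose(got, want, atol=1e-10)


def test_dendrogram_heights_are_monotone(rng):
    x = rng.normal(size=(40, 5))
    tree = hierarchical_average(pairwise_distance(x, "euclidean"))
    assert np.all(np.diff(tree.heights) >= -1e-12)


def test_asymmetric_input_rejected():
    bad = np.array([[0.0, 1.0], [2.0, 0.0]])
    with pytest.raises(ValueError, match="symmetric"):
        hierarchical_average(DistanceMatrix(values=(bad + 0), metric="euclidean"))


def test_cut_to_k_extremes(rng):
    x = rng.normal(size=(12, 3))
    tree = hierarchical_average(pairwise_distance(x, "euclidean"))
    assert cut_to_k(tree, 1).k == 1
    singletons = cut_to_k(tree, 12)
    assert sorted(singletons.labels) == list(range(1, 13))
    for bad_k in (0, 13):
        with pytest.raises(ValueError):
            cut_to_k(tree, bad_k)


def test_cut_labels_contiguous_no_empty(rng):
    x = rng.normal(size=(30, 4))
    tree = hierarchical_average(pairwise_distance(x, "euclidean"))
    for k in (2, 5, 9):
        labels = cut_to_k(tree, k).labels
        assert set(labels) == set(range(1, k + 1))


def test_project_labels_lookup_and_compaction(rng):
    proto = Partition(labels=[1, 2], method="x", k=2)
    cells = project_labels(proto, np.array([0, 1, 0]))
    assert list(cells.labels) == [1, 2, 1]
    # all cells on one prototype: the other cluster is dropped with a warning
    proto3 = Partition(labels=[1, 2, 2], method="x", k=2)
    with pytest.warns(UserWarning, match="re-compacted"):
        collapsed = project_labels(proto3, np.array([2, 2, 2, 2]))
    assert list(collapsed.labels) == [1, 1, 1, 1]
    with pytest.raises(ValueError):
        project_labels(proto, np.array([0, 5]))
    # random case: elementwise lookup oracle
    labels = rng.integers(1, 4, size=9)
    proto_r = Partition(labels=labels, method="x")
    bmu = rng.integers(0, 9, size=50)
    got = project_labels(proto_r, bmu)
    raw = labels[bmu]
    # compaction preserves co-membership structure exactly
    assert adjusted_rand_index(got.labels, raw) == 1.0


def test_fusesom_recovers_planted_mixture(small_dataset):
    truth = Partition(labels=np.asarray(small_dataset.annotations, dtype=object))
    result = fusesom_cluster(small_dataset, k=4, config=RunConfig(seed=2))
    assert adjusted_rand_index(result.partition, truth) >= 0.9
    # intermediates are returned for audit
    assert result.som.prototypes.shape[1] == small_dataset.n_markers
    assert result.fused.n == result.som.prototypes.shape[0]
    assert result.tree.n_leaves == result.fused.n


def test_fusesom_rejects_k_below_two(small_dataset):
    with pytest.raises(ValueError):
        fusesom_cluster(small_dataset, k=1)


def test_fusesom_deterministic_and_row_order_equivariant(small_dataset):
    cfg = RunConfig(seed=5, grid_side=5)
    r1 = fusesom_cluster(small_dataset, k=4, config=cfg)
    r2 = fusesom_cluster(small_dataset, k=4, config=cfg)
    assert np.array_equal(r1.partition.labels, r2.partition.labels)
    # permuting marker columns changes nothing about the partition
    perm = np.random.default_rng(0).permutation(small_dataset.n_markers)
    shuffled = type(small_dataset)(
        values=small_dataset.values[:, perm],
        cell_ids=list(small_dataset.cell_ids),
        marker_names=[small_dataset.marker_names[j] for j in perm],
        annotations=small_dataset.annotations,
    )
    r3 = fusesom_cluster(shuffled, k=4, config=cfg)
    assert adjusted_rand_index(r3.partition, r1.partition) == pytest.approx(1.0)
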