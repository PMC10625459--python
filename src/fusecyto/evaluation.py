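"""External clustering-evaluation indices: ARI, NMI, Fowlkes–Mallows, F-measure.

All four indices compare two partitions of the same items and equal 1 when
the partitions are identical as set partitions. ARI, NMI and FM are symmetric
in their arguments. For the F-measure the convention is that the first
argument is the algorithm's prediction and the second the reference
annotation; precision and recall are defined over unordered item pairs
(pair-counting definition), sharing the TP/FP/FN vocabulary with the
Fowlkes–Mallows index, so F <= FM always (harmonic <= geometric mean).

Degenerate-input policy: when the ARI denominator is zero the result is 1 if
the partitions are identical as set partitions and 0 otherwise; NMI with two
zero-entropy (single-cluster) partitions is defined as 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class Partition:
    """Integer cluster label per item plus provenance."""

    labels: np.ndarray
    method: str = ""
    k: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 1 or self.labels.size == 0:
            raise ValueError("labels must be a nonempty 1-D array")
        if not self.k:
            self.k = int(len(np.unique(self.labels)))

    def __len__(self) -> int:
        return self.labels.size


@dataclass
class ContingencyTable:
    counts: np.ndarray
    n: int


@dataclass
class PairConfusion:
    """Counts over all n(n-1)/2 unordered item pairs.

    TP: pairs together in both partitions; FP: together in the prediction
    only; FN: together in the truth only; TN: apart in both.
    """

    TP: int
    FP: int
    FN: int
    TN: int


def _labels(p) -> np.ndarray:
    return np.asarray(getattr(p, "labels", p))


def contingency(x, y) -> ContingencyTable:
    """Cross-tabulate two partitions: counts[i, j] = #items in group i of x and j of y."""
    lx, ly = _labels(x), _labels(y)
    if lx.size != ly.size:
        raise ValueError("partitions must have equal length")
    _, xi = np.unique(lx, return_inverse=True)
    _, yi = np.unique(ly, return_inverse=True)
    counts = np.zeros((xi.max() + 1, yi.max() + 1), dtype=np.int64)
    np.add.at(counts, (xi, yi), 1)
    return ContingencyTable(counts=counts, n=int(lx.size))


def pair_confusion(x, y) -> PairConfusion:
    """Pair-counting confusion between prediction x and truth y."""
    tab = contingency(x, y)
    c = tab.counts
    n = tab.n

    def _pairs(v):
        return int(np.sum(v.astype(np.int64) * (v.astype(np.int64) - 1) // 2))

    tp = _pairs(c)
    same_x = _pairs(c.sum(axis=1))
    same_y = _pairs(c.sum(axis=0))
    total = n * (n - 1) // 2
    fp = same_x - tp
    fn = same_y - tp
    tn = total - tp - fp - fn
    return PairConfusion(TP=tp, FP=fp, FN=fn, TN=tn)


def _identical_as_set_partitions(x, y) -> bool:
    c = contingency(x, y).counts
    return bool(np.all((c > 0).sum(axis=1) == 1) and np.all((c > 0).sum(axis=0) == 1))


def adjusted_rand_index(x, y) -> float:
    """Rand index corrected for chance agreement between two partitions."""
    tab = contingency(x, y)
    if tab.n < 2:
        raise ValueError("ARI requires at least 2 items")
    c = tab.counts

    def _pairs(v):
        v = v.astype(np.int64)
        return np.sum(v * (v - 1) // 2)

    sum_ij = _pairs(c)
    sum_a = _pairs(c.sum(axis=1))
    sum_b = _pairs(c.sum(axis=0))
    total = tab.n * (tab.n - 1) // 2
    expected = sum_a * sum_b / total
    max_index = (sum_a + sum_b) / 2.0
    denom = max_index - expected
    if denom == 0:
        return 1.0 if _identical_as_set_partitions(x, y) else 0.0
    return float((sum_ij - expected) / denom)


def normalized_mutual_information(x, y) -> float:
    """2 I(X,Y) / (H(X) + H(Y)) with natural-log entropies from empirical frequencies."""
    tab = contingency(x, y)
    c = tab.counts.astype(float)
    n = tab.n
    pxy = c / n
    px = pxy.sum(axis=1)
    py = pxy.sum(axis=0)

    def _entropy(p):
        p = p[p > 0]
        return float(-np.sum(p * np.log(p)))

    hx, hy = _entropy(px), _entropy(py)
    if hx + hy == 0:
        return 1.0  # both single-cluster partitions
    nz = pxy > 0
    mi = float(np.sum(pxy[nz] * (np.log(pxy[nz]) - np.log(np.outer(px, py)[nz]))))
    return float(2.0 * max(mi, 0.0) / (hx + hy))


def fowlkes_mallows(x, y) -> float:
    """Geometric mean of pairwise precision and recall: TP / sqrt((TP+FP)(TP+FN))."""
    pc = pair_confusion(x, y)
    if pc.TP + pc.FP == 0 and pc.TP + pc.FN == 0:
        raise ValueError("no within-cluster pairs in either partition")
    if pc.TP == 0:
        return 0.0
    return float(pc.TP / np.sqrt(float(pc.TP + pc.FP) * float(pc.TP + pc.FN)))


def f_measure(x, y) -> float:
    """Harmonic mean of pairwise precision and recall (x = prediction, y = truth)."""
    pc = pair_confusion(x, y)
    if pc.TP + pc.FP == 0 and pc.TP + pc.FN == 0:
        raise ValueError("no within-cluster pairs in either partition")
    precision = pc.TP / (pc.TP + pc.FP) if pc.TP + pc.FP else 0.0
    recall = pc.TP / (pc.TP + pc.FN) if pc.TP + pc.FN else 0.0
    if precision + recall == 0:
        return 0.0
    return float(2.0 * precision * recall / (precision + recall))


INDEX_FUNCTIONS = {
    "ARI": adjusted_rand_index,
    "NMI": normalized_mutual_information,
    "FM": fowlkes_mallows,
    "F": f_measure,
}


def score_all(prediction, truth) -> dict[str, float]:
    """All four indices of a prediction against reference annotations."""
    return {name: fn(prediction, truth) for name, fn in INDEX_FUNCTIONS.items()}
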