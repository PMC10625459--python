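import numpy as np
import pytest

from fusecyto.k_estimation import (
    dip_pvalue_table,
    dip_statistic,
    dip_test,
    discriminant_k,
    estimate_k,
    gap_statistic,
    jump_statistic,
    max_clusterability_projection,
    silhouette_statistic,
    slope_statistic,
    wcd_elbow,
    _holm,
)
from fusecyto.metrics import pairwise_distance
from oracles import lp_dip


def _blobs(rng, k, per=30, dim=6, sep=12.0):
    centers = rng.normal(size=(k, dim))
    centers = centers / np.linalg.norm(centers, axis=1, keepdims=True)
    centers *= sep * np.arange(1, k + 1)[:, None] / 2.0
    return np.concatenate([rng.normal(c, 1.0, size=(per, dim)) for c in centers])


# --- dip statistic ---------------------------------------------------------

def test_dip_matches_lp_oracle_on_small_samples(rng):
    for trial in range(30):
        n = int(rng.integers(4, 13))
        if trial % 3 == 0:
            x = rng.integers(0, 4, size=n).astype(float)  # heavy ties
            if len(np.unique(x)) == 1:
                continue
        else:
            x = rng.normal(size=n)
        assert dip_statistic(x) == pytest.approx(lp_dip(x), abs=1e-10)


def test_dip_two_atom_sample_attains_upper_bound():
    x = np.r_[np.zeros(20), np.ones(20)]
    assert dip_statistic(x) == pytest.approx(0.25, abs=1e-14)


def test_dip_bounds_and_unimodal_vs_bimodal(rng):
    gauss = rng.normal(size=400)
    bimodal = np.r_[rng.normal(size=200), rng.normal(8, 1, size=200)]
    d1, d2 = dip_statistic(gauss), dip_statistic(bimodal)
    assert 0 < d1 <= 0.25 and 0 < d2 <= 0.25
    assert d2 > 4 * d1
    with pytest.raises(ValueError):
        dip_statistic([1.0, 2.0, 3.0])


def test_dip_test_null_acceptance_on_gaussians():
    accept = 0
    for s in range(8):
        x = np.random.default_rng(700 + s).normal(size=300)
        res = dip_test(x, n_boot=60, seed=1)
        accept += res.p_value > 0.1
    assert accept >= 7


def test_dip_pvalues_approximately_uniform_under_null():
    rng = np.random.default_rng(41)
    pvals = [dip_pvalue_table(dip_statistic(rng.uniform(size=64)), 64) for _ in range(200)]
    from scipy.stats import kstest

    assert kstest(pvals, "uniform").pvalue > 0.01


# --- WSS / silhouette estimators -------------------------------------------

def test_gap_statistic_recovers_blob_count_and_single_gaussian():
    hits = 0
    for s in range(10):
        r = np.random.default_rng(50 + s)
        est = gap_statistic(_blobs(r, 3), k_range=range(1, 9), B=20, seed=s)
        assert len(est.curve) == 8
        hits += est.k_hat == 3
    assert hits >= 8
    single = np.random.default_rng(0).normal(size=(80, 6))
    assert gap_statistic(single, k_range=range(1, 9), B=20, seed=0).k_hat == 1


def test_gap_rejects_degenerate_reference(rng):
    x = rng.normal(size=(30, 3))
    x[:, 1] = 2.0
    with pytest.raises(ValueError, match="zero range"):
        gap_statistic(x, k_range=range(1, 5), B=10, seed=0)


def test_silhouette_statistic_and_per_point_oracle(rng):
    pts = _blobs(rng, 2, per=20)
    d = pairwise_distance(pts, "euclidean")
    est = silhouette_statistic(d, k_range=range(2, 7))
    assert est.k_hat == 2
    assert est.curve[2] > 0.7
    # brute-force a/b silhouette for the k=2 cut
    from fusecyto.clustering import cut_to_k, hierarchical_average

    labels = cut_to_k(hierarchical_average(d), 2).labels
    vals = []
    for i in range(len(pts)):
        same = [j for j in range(len(pts)) if labels[j] == labels[i] and j != i]
        a = np.mean([d.values[i, j] for j in same])
        b = min(
            np.mean([d.values[i, j] for j in range(len(pts)) if labels[j] == lab])
            for lab in set(labels) - {labels[i]}
        )
        vals.append((b - a) / max(a, b))
    from sklearn.metrics import silhouette_score

    assert silhouette_score(d.values, labels, metric="precomputed") == pytest.approx(
        np.mean(vals), abs=1e-10
    )


def test_jump_statistic_blobs_and_curve_shape(rng):
    hits = 0
    for s in range(10):
        r = np.random.default_rng(150 + s)
        est = jump_statistic(_blobs(r, 3), k_range=range(1, 9))
        assert len(est.curve) == 8
        hits += est.k_hat == 3
    assert hits >= 8


def test_slope_statistic_four_blobs(rng):
    hits = 0
    for s in range(10):
        r = np.random.default_rng(250 + s)
        d = pairwise_distance(_blobs(r, 4, per=20), "euclidean")
        est = slope_statistic(d, k_range=range(2, 9))
        assert len(est.curve) == 6  # one fewer than |k_range|
        hits += est.k_hat == 4
    assert hits >= 8


def test_wcd_elbow_blobs_and_flat_curve_rule(rng):
    hits = 0
    for s in range(10):
        r = np.random.default_rng(350 + s)
        est = wcd_elbow(_blobs(r, 3), k_range=range(2, 9))
        curve = np.array([est.curve[k] for k in sorted(est.curve)])
        assert np.all(np.diff(curve) <= 1e-9)  # nonincreasing on separated blobs
        hits += est.k_hat == 3
    assert hits >= 8
    with pytest.raises(ValueError):
        wcd_elbow(rng.normal(size=(20, 3)), k_range=range(2, 4))


# --- discriminant method ----------------------------------------------------

def test_projection_finds_displacement_axis(rng):
    a = rng.normal(size=(200, 2))
    b = rng.normal(size=(200, 2)) + np.array([6.0, 0.0])
    pts = np.vstack([a, b])
    split = np.r_[np.zeros(200), np.ones(200)]
    proj = max_clusterability_projection(pts, split)
    # recover the direction via least squares against the coordinates
    w, *_ = np.linalg.lstsq(pts - pts.mean(0), proj - proj.mean(), rcond=None)
    w = w / np.linalg.norm(w)
    assert abs(w[0]) >= 0.99


def test_projection_degenerate_and_equivariance(rng):
    pts = rng.normal(size=(20, 3))
    split = np.r_[np.zeros(10), np.ones(10)]
    shifted = pts.copy()
    # identical class means: still produces projections without error
    proj = max_clusterability_projection(shifted, split)
    assert proj.shape == (20,)
    # rotation of the data rotates the direction: projections are preserved
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    p1 = max_clusterability_projection(pts + [5, 0, 0] * split[:, None], split)
    p2 = max_clusterability_projection((pts + [5, 0, 0] * split[:, None]) @ q, split)
    assert np.allclose(p1, p2, atol=1e-6)
    with pytest.raises(ValueError):
        max_clusterability_projection(pts, np.r_[np.zeros(19), np.ones(1)])


def test_holm_step_down():
    p = np.array([0.001, 0.01, 0.04, 0.5])
    rejected = _holm(p, alpha=0.05)
    # 0.001 <= .05/4 and 0.01 <= .05/3, then 0.04 > .05/2 stops the chain
    assert list(rejected) == [True, True, False, False]
    # step-down is at least as powerful as Bonferroni
    assert list(_holm(np.array([0.012, 0.03]), alpha=0.05)) == [True, True]


def test_discriminant_k_blobs_and_null():
    r = np.random.default_rng(77)
    est = discriminant_k(_blobs(r, 3, per=30), seed=0)
    assert est.k_hat == 3
    nulls = 0
    for s in range(10):
        single = np.random.default_rng(900 + s).normal(size=(100, 5))
        nulls += discriminant_k(single, seed=s).k_hat == 1
    assert nulls >= 9
    # alpha -> 0 forces a single cluster
    assert discriminant_k(_blobs(r, 3), alpha=1e-9, seed=0).k_hat == 1
    with pytest.raises(ValueError):
        discriminant_k(np.random.default_rng(0).normal(size=(5, 3)))


def test_estimate_k_dispatch_and_range(blobs3):
    pts, _ = blobs3
    for method in ("gap", "silhouette", "jump", "slope", "wcd", "discriminant"):
        est = estimate_k(pts, method, k_range=range(2, 9), seed=1)
        assert 1 <= est.k_hat <= 8, method
    with pytest.raises(ValueError):
        estimate_k(pts, "bic")
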