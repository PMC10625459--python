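import numpy as np
import pytest
from scipy.spatial.distance import cdist

from fusecyto.som import (
    SOMGrid,
    assign_bmu,
    estimate_grid_side,
    fit_som,
    quantization_error,
    significant_eigenvalues,
)


def test_grid_geometry():
    g = SOMGrid(3)
    assert g.n_prototypes == 9
    assert g.positions.shape == (9, 2)
    with pytest.raises(ValueError):
        SOMGrid(1)


def test_assign_bmu_matches_scan_oracle_and_tie_rule(rng):
    protos = rng.normal(size=(12, 5))
    data = rng.normal(size=(40, 5))
    got = assign_bmu(protos, data)
    want = np.array([np.argmin([np.linalg.norm(r - p) for p in protos]) for r in data])
    assert np.array_equal(got, want)
    # a cell equal to a prototype maps to it
    assert assign_bmu(protos, protos[7])[0] == 7
    # equidistant between two prototypes -> lower index wins
    p = np.array([[0.0], [2.0]])
    assert assign_bmu(p, np.array([[1.0]]))[0] == 0
    with pytest.raises(ValueError):
        assign_bmu(protos, rng.normal(size=(3, 4)))


def test_quantization_error_closed_forms(rng):
    protos = rng.normal(size=(6, 3))
    assert quantization_error(protos, protos) == 0.0
    pts = np.array([[0.0, 0.0], [3.0, 0.0], [0.0, 3.0]])
    centroid = pts.mean(axis=0, keepdims=True)
    expected = float(np.mean(np.linalg.norm(pts - centroid, axis=1)))
    assert quantization_error(centroid, pts) == pytest.approx(expected)
    # adding a duplicated prototype never increases QE
    more = np.vstack([protos, protos[0]])
    data = rng.normal(size=(30, 3))
    assert quantization_error(more, data) <= quantization_error(protos, data) + 1e-12


def test_fit_som_identical_cells_converge_to_point(rng):
    v = np.array([2.0, -1.0, 0.5])
    data = np.tile(v, (50, 1))
    model = fit_som(data, SOMGrid(2), epochs=12, seed=0)
    assert np.allclose(model.prototypes, v, atol=1e-6)


def test_fit_som_splits_two_blobs_and_reduces_qe(rng):
    blob_a = rng.normal(0.0, 0.5, size=(100, 4))
    blob_b = rng.normal(10.0, 0.5, size=(100, 4))
    data = np.vstack([blob_a, blob_b])
    model = fit_som(data, SOMGrid(2), epochs=10, seed=1)
    trace = model.quantization_error_trace
    assert trace[-1] < trace[0]
    near_a = np.sum(np.linalg.norm(model.prototypes - 0.0, axis=1) < 5)
    assert 1 <= near_a <= 3  # prototypes split across the blobs


def test_fit_som_deterministic_under_seed(rng):
    data = rng.normal(size=(80, 6))
    m1 = fit_som(data, SOMGrid(3), epochs=5, seed=9)
    m2 = fit_som(data, SOMGrid(3), epochs=5, seed=9)
    assert np.array_equal(m1.prototypes, m2.prototypes)
    assert np.array_equal(m1.bmu, m2.bmu)


def test_fit_som_preconditions(rng):
    data = rng.normal(size=(8, 3))
    with pytest.raises(ValueError, match="prototypes"):
        fit_som(data, SOMGrid(3), epochs=3, seed=0)
    with pytest.raises(ValueError, match="epochs"):
        fit_som(rng.normal(size=(30, 3)), SOMGrid(2), epochs=0, seed=0)


def test_topology_preservation_on_2d_manifold(rng):
    """Grid-adjacent prototypes are closer in feature space than non-adjacent."""
    u = rng.uniform(-1, 1, size=(1500, 2))
    basis = rng.normal(size=(2, 10))
    data = u @ basis + rng.normal(scale=0.05, size=(1500, 10))
    model = fit_som(data, SOMGrid(5), epochs=10, seed=2)
    pos = model.grid.positions
    grid_d = cdist(pos, pos, metric="cityblock")
    feat_d = cdist(model.prototypes, model.prototypes)
    adjacent = feat_d[grid_d == 1]
    nonadjacent = feat_d[(grid_d > 1) & (grid_d > 0)]
    assert adjacent.mean() < nonadjacent.mean()


def test_grid_side_floor_and_mapping(rng):
    noise = rng.normal(size=(400, 10))
    assert estimate_grid_side(noise) == 5  # k_sig <= 1 floors at the minimum side
    with pytest.raises(ValueError, match="zero-variance"):
        constant = np.hstack([noise, np.ones((400, 1))])
        significant_eigenvalues(constant)


def test_significant_eigenvalues_detects_planted_spikes():
    hits = 0
    for s in range(10):
        r = np.random.default_rng(500 + s)
        z = r.normal(size=(1500, 20))
        for i in range(5):
            u = np.zeros(20)
            u[i * 4 : (i + 1) * 4] = 1.0
            z += np.outer(r.normal(size=1500), u)
        hits += significant_eigenvalues(z) >= 5
    assert hits >= 9


def test_significant_eigenvalues_scale_invariant(rng):
    x = rng.normal(size=(800, 15)) * 37.2
    y = x / 37.2
    assert significant_eigenvalues(x) == significant_eigenvalues(y)
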