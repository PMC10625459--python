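import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=30)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def blobs3():
    """Three well-separated isotropic blobs in 8 dimensions, 30 points each."""
    r = np.random.default_rng(7)
    centers = np.zeros((3, 8))
    centers[1, :] = 12.0
    centers[2, :4] = 24.0
    pts = np.concatenate([r.normal(c, 1.0, size=(30, 8)) for c in centers])
    labels = np.repeat([1, 2, 3], 30)
    return pts, labels


@pytest.fixture
def small_dataset():
    """A modest simulated cytometry matrix with planted annotations."""
    from fusecyto import SimulationSpec, simulate_cytometry

    return simulate_cytometry(
        SimulationSpec(n_cells=600, n_markers=12, n_types=4, mean_separation=8.0, seed=3)
    )
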