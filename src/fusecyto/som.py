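"""Self-organizing map training and data-driven grid sizing.

The SOM reduces N cells to P = side x side prototype vectors on a 2-D
rectangular grid while preserving topology: nearby grid nodes end up
representing nearby regions of marker space. Clustering then operates on the
prototypes rather than the cells, and labels are projected back through each
cell's best-matching unit (BMU).

Grid sizing follows a random-matrix argument: the number of eigenvalues of
the column-standardized covariance matrix that are significantly larger than
expected under white noise — judged against the Tracy–Widom TW1 law for the
largest eigenvalue, tested sequentially with Patterson-style re-normalization
— counts the "real" structure axes, and the grid side is chosen to give a
fixed number of prototypes per significant component.

Training is batch SOM: each epoch assigns every cell to its nearest
prototype (Euclidean) and then replaces every prototype by the Gaussian
neighborhood-weighted mean of all cells, with the neighborhood radius
decaying linearly from max(side)/2 to 0.5 over epochs. Prototypes are
initialized on the span of the first two principal axes plus a small seeded
jitter, so the whole fit is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

# Upper-tail critical values of the Tracy-Widom TW1 (GOE) distribution, as
# published in the statistical-genetics literature on significant principal
# components (Johnstone 2001; Patterson, Price & Reich 2006).
TW1_CRITICAL = {0.05: 0.9793, 0.01: 2.0234, 0.001: 3.2724}


@dataclass
class SOMGrid:
    """Rectangular prototype grid; default square, at least 2 x 2."""

    side_x: int
    side_y: int | None = None
    topology: str = "rectangular"

    def __post_init__(self) -> None:
        if self.side_y is None:
            self.side_y = self.side_x
        if self.side_x < 2 or self.side_y < 2:
            raise ValueError("grid must be at least 2 x 2 (P >= 4)")
        if self.topology != "rectangular":
            raise ValueError("only rectangular topology is supported")

    @property
    def n_prototypes(self) -> int:
        return self.side_x * self.side_y

    @property
    def positions(self) -> np.ndarray:
        """P x 2 array of (row, col) grid coordinates, row-major order."""
        gx, gy = np.meshgrid(
            np.arange(self.side_x), np.arange(self.side_y), indexing="ij"
        )
        return np.column_stack([gx.ravel(), gy.ravel()]).astype(float)


@dataclass
class SOMModel:
    grid: SOMGrid
    prototypes: np.ndarray
    bmu: np.ndarray  # per-cell best-matching prototype index, 0-based
    quantization_error_trace: list[float] = field(default_factory=list)
    seed: int = 0


def _johnstone_params(n: int, p: int) -> tuple[float, float]:
    """Centering and scaling for the largest eigenvalue of a white Wishart.

    Uses the half-integer-corrected constants (n - 1/2, p - 1/2 inside the
    square roots), which converge to TW1 at second order and are noticeably
    more accurate in the upper tail at small p than the original constants.
    """
    a = np.sqrt(n - 0.5) + np.sqrt(p - 0.5)
    mu = a * a
    sigma = a * (1.0 / np.sqrt(n - 0.5) + 1.0 / np.sqrt(p - 0.5)) ** (1.0 / 3.0)
    return mu, sigma


def _tw_critical(alpha: float) -> float:
    if alpha not in TW1_CRITICAL:
        raise ValueError(
            f"alpha must be one of {sorted(TW1_CRITICAL)}; got {alpha}"
        )
    return TW1_CRITICAL[alpha]


def significant_eigenvalues(data: np.ndarray, alpha: float = 0.05) -> int:
    """Count covariance eigenvalues significantly above the white-noise null.

    Eigenvalues of the M x M covariance of the column-centered data are
    tested largest-first. At step i the remaining spectrum is rescaled to
    unit mean (making the test invariant to the overall noise scale), the
    candidate eigenvalue is Johnstone-standardized with the half-corrected
    constants at effective dimension M - i, and testing stops at the first
    statistic below the TW1 critical value at ``alpha``.

    Columns are centered but deliberately not variance-standardized: fixing
    every column variance pins the spectrum's trace and visibly deflates the
    largest-eigenvalue fluctuation at moderate M, breaking the Tracy-Widom
    calibration. Markers on wildly different scales should be normalized
    upstream, consistent with this package applying no internal transforms.
    """
    x = np.asarray(getattr(data, "values", data), dtype=float)
    n, m = x.shape
    if m < 2:
        raise ValueError("need at least 2 markers")
    sd = x.std(axis=0, ddof=1)
    if np.any(sd == 0):
        j = int(np.where(sd == 0)[0][0])
        names = list(getattr(data, "marker_names", []) or [])
        label = names[j] if names else f"column {j}"
        raise ValueError(f"zero-variance marker {label!r}; remove it before grid sizing")
    ev = np.linalg.eigvalsh(np.cov(x, rowvar=False))[::-1]
    ev = np.clip(ev, 0.0, None)

    crit = _tw_critical(alpha)
    k_sig = 0
    for i in range(m - 1):
        rest = ev[i:]
        p_eff = m - i
        # rescale remaining spectrum to unit mean under the shrunk null
        scale = p_eff / rest.sum() if rest.sum() > 0 else 0.0
        lam = ev[i] * scale * (n - 1)
        mu, sigma = _johnstone_params(n - 1, p_eff)
        if (lam - mu) / sigma > crit:
            k_sig += 1
        else:
            break
    return k_sig


def estimate_grid_side(
    data,
    alpha: float = 0.05,
    prototypes_per_signal: float = 5.0,
    min_side: int = 5,
) -> int:
    """Map the significant-eigenvalue count to a square SOM grid side.

    side = max(min_side, ceil(sqrt(prototypes_per_signal * k_sig))): each
    significant structure axis earns ``prototypes_per_signal`` prototypes,
    floored so tiny or structureless data still gets a workable grid.
    """
    k_sig = significant_eigenvalues(data, alpha=alpha)
    side = int(np.ceil(np.sqrt(prototypes_per_signal * max(k_sig, 1))))
    return max(min_side, side)


def _init_prototypes(x: np.ndarray, grid: SOMGrid, rng: np.random.Generator) -> np.ndarray:
    """Linear initialization: grid spanned by the first two principal axes."""
    mean = x.mean(axis=0)
    xc = x - mean
    # top-2 right singular vectors and singular values
    _, s, vt = np.linalg.svd(xc, full_matrices=False)
    scale = s[:2] / np.sqrt(max(x.shape[0] - 1, 1))
    if len(scale) < 2:  # M == 1 guarded upstream; keep safe anyway
        scale = np.r_[scale, scale]
    pos = grid.positions
    u = np.zeros((pos.shape[0], 2))
    for d, side in enumerate((grid.side_x, grid.side_y)):
        u[:, d] = (pos[:, d] / max(side - 1, 1) - 0.5) * 2.0
    proto = mean + (u * scale * 2.0) @ vt[:2]
    jitter = rng.normal(scale=1e-4 * (x.std() + 1e-12), size=proto.shape)
    return proto + jitter


def assign_bmu(model_or_prototypes, data: np.ndarray) -> np.ndarray:
    """Map each row to the index of its nearest prototype (Euclidean).

    Ties are broken toward the lowest prototype index (np.argmin convention).
    """
    prototypes = getattr(model_or_prototypes, "prototypes", model_or_prototypes)
    prototypes = np.asarray(prototypes, dtype=float)
    data = np.asarray(getattr(data, "values", data), dtype=float)
    if data.ndim == 1:
        data = data[None, :]
    if data.shape[1] != prototypes.shape[1]:
        raise ValueError(
            f"data has {data.shape[1]} markers but prototypes have {prototypes.shape[1]}"
        )
    return np.argmin(cdist(data, prototypes), axis=1)


def quantization_error(model_or_prototypes, data: np.ndarray) -> float:
    """Mean Euclidean distance from each row to its best-matching prototype."""
    prototypes = getattr(model_or_prototypes, "prototypes", model_or_prototypes)
    prototypes = np.asarray(prototypes, dtype=float)
    data = np.asarray(getattr(data, "values", data), dtype=float)
    d = cdist(data, prototypes)
    return float(d.min(axis=1).mean())


def fit_som(
    data,
    grid: SOMGrid,
    epochs: int = 10,
    seed: int = 0,
) -> SOMModel:
    """Train a batch SOM on a cell-by-marker matrix.

    Per epoch: assign BMUs, then set every prototype to the neighborhood-
    kernel-weighted mean of all cells, where the Gaussian kernel acts on grid
    coordinates with a radius decaying linearly from max(side)/2 to 0.5.
    Prototypes that attract no kernel mass keep their previous value. The fit
    is fully deterministic given the seed (used only for the init jitter).
    """
    x = np.asarray(getattr(data, "values", data), dtype=float)
    if epochs < 1:
        raise ValueError("epochs must be >= 1")
    n = x.shape[0]
    if grid.n_prototypes > n:
        raise ValueError(
            f"grid has {grid.n_prototypes} prototypes but only {n} cells; "
            "use a smaller grid"
        )
    rng = np.random.default_rng(seed)
    proto = _init_prototypes(x, grid, rng)
    pos = grid.positions
    grid_d2 = cdist(pos, pos, metric="sqeuclidean")  # P x P grid distances

    r_start = max(grid.side_x, grid.side_y) / 2.0
    r_end = 0.5
    qe_trace: list[float] = []
    bmu = assign_bmu(proto, x)
    for epoch in range(epochs):
        qe_trace.append(quantization_error(proto, x))
        frac = epoch / max(epochs - 1, 1)
        radius = r_start + (r_end - r_start) * frac
        kernel = np.exp(-grid_d2 / (2.0 * radius * radius))  # P x P
        # counts and sums of cells per BMU node
        counts = np.bincount(bmu, minlength=grid.n_prototypes).astype(float)
        sums = np.zeros_like(proto)
        np.add.at(sums, bmu, x)
        weight = kernel @ counts  # kernel mass landing on each prototype
        numer = kernel @ sums
        nonzero = weight > 1e-300
        proto[nonzero] = numer[nonzero] / weight[nonzero, None]
        bmu = assign_bmu(proto, x)
    qe_trace.append(quantization_error(proto, x))
    return SOMModel(
        grid=grid,
        prototypes=proto,
        bmu=bmu,
        quantization_error_trace=qe_trace,
        seed=seed,
    )
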