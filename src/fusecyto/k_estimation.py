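"""Estimators for the number of clusters, operating on SOM prototypes.

Six estimators are provided: the Gap, Silhouette, Jump, Slope and
within-cluster-distance (WCD) statistics, and a Discriminant method that
couples the average-linkage dendrogram with a maximum-clusterability
projection and Hartigan's dip test of unimodality at every internal node,
controlling the family-wise error rate across nodes.

All estimators derive their per-k partitions by cutting one average-linkage
tree (the same clustering path used for the final solution) rather than
re-running a flat clusterer per k, so the estimate is consistent with the
clustering it feeds.

The dip statistic is implemented exactly from its definition
``dip(F) = min over unimodal G of sup |F_n - G|``: for every placement of
the mode (an atom at a data value, or inside a gap between values) the
minimal sup-distance decomposes into a left convex-minorant fit and a right
concave-majorant fit, each solvable in closed form as half the maximal gap
between the empirical CDF's upper staircase corners and the convex hull of
its lower corners. The dip is half the minimum over placements of the
larger one-sided deviation. Mode atoms are excluded from their own
deviation term, which is what lets a unimodal law absorb one arbitrarily
large jump.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import linkage
from sklearn.metrics import silhouette_score

from .clustering import Dendrogram, cut_to_k, hierarchical_average
from .metrics import DistanceMatrix, pairwise_distance


@dataclass
class KEstimate:
    method: str
    k_hat: int
    curve: dict[int, float]
    alpha: float | None = None
    details: dict = field(default_factory=dict)


@dataclass
class DipResult:
    statistic: float
    p_value: float
    n: int


# ---------------------------------------------------------------------------
# Hartigan's dip statistic
# ---------------------------------------------------------------------------

def _left_deviation_profile(xv: np.ndarray, lower: np.ndarray, upper: np.ndarray):
    """C[k] = max_{t<k} (upper[t] - hull_k(x_t)) for the convex minorant of
    the lower staircase corners of the first k+1 distinct values.

    hull_k is the greatest convex minorant of the points (x_t, lower[t]),
    t <= k. C[k] is the (doubled) minimal sup-error of fitting a convex
    increasing sub-distribution to the ECDF left of a mode atom at x_k.
    """
    K = len(xv)
    C = np.zeros(K)
    stack = [0]
    dmax = {0: float(upper[0] - lower[0])}  # running max dev at t <= vertex
    for k in range(1, K):
        while len(stack) >= 2:
            i, j = stack[-2], stack[-1]
            if (lower[k] - lower[j]) * (xv[j] - xv[i]) <= (
                lower[j] - lower[i]
            ) * (xv[k] - xv[j]):
                stack.pop()
            else:
                break
        p = stack[-1]
        if k - p > 1:
            t = np.arange(p + 1, k)
            chord = lower[p] + (lower[k] - lower[p]) * (xv[t] - xv[p]) / (
                xv[k] - xv[p]
            )
            seg = float(np.max(upper[t] - chord))
        else:
            seg = 0.0
        C[k] = max(dmax[p], seg)
        dmax[k] = max(C[k], float(upper[k] - lower[k]))
        stack.append(k)
    return C


class _ModeCoupling:
    """Monotonicity coupling of the two one-sided fits at a mode atom.

    For a mode atom at knot k and sup-distance d, convexity propagates any
    rise forced between two left tubes: the slope out of knot t2 is at least
    (upper[t2]-d - (lower[t1]+d)) / (x2-x1), so the minimal left-limit value
    at x_k is the upper envelope of the corresponding rays (floored at 0).
    Mirroring gives the maximal CDF value the right (concave) side allows at
    x_k (capped at 1). Feasibility requires arrival <= departure at some
    admissible k; the gap is piecewise linear and strictly decreasing in d.
    """

    def __init__(self, xv, lower, upper):
        K = len(xv)
        tril = np.tril(np.ones((K, K), dtype=bool), k=-1)  # [t2, t1], t1 < t2
        dx = xv[:, None] - xv[None, :]
        with np.errstate(divide="ignore"):
            self.inv_dx = np.where(tril, 1.0 / dx, 0.0)
        self.gap_lu = np.where(tril, upper[:, None] - lower[None, :], 0.0)
        self.xv, self.lower, self.upper = xv, lower, upper
        self.K = K
        self.triu = tril.T  # [t2, k], t2 < k

    def _one_side(self, d):
        """(value, d-slope) of the forced arrival at every knot, from the left."""
        slopes = (self.gap_lu - 2.0 * d) * self.inv_dx
        t1 = np.argmax(slopes, axis=1)
        sigma = slopes[np.arange(self.K), t1]
        live = sigma > 0.0
        sigma = np.where(live, sigma, 0.0)
        # d-derivative of sigma for the active pair
        dsigma = np.where(live, -2.0 * self.inv_dx[np.arange(self.K), t1], 0.0)
        # rays[t2, k] = upper[t2] - d + sigma[t2] * (x_k - x_t2)
        rays = np.where(
            self.triu,
            (self.upper - d - sigma * self.xv)[:, None] + np.outer(sigma, self.xv),
            -np.inf,
        )
        t2 = np.argmax(rays, axis=0)
        value = rays[t2, np.arange(self.K)]
        dvalue = -1.0 + dsigma[t2] * (self.xv - self.xv[t2])
        value[0], dvalue[0] = -np.inf, 0.0
        clamped = value < 0.0
        return np.where(clamped, 0.0, value), np.where(clamped, 0.0, dvalue)

    def gap(self, d, ok):
        """(min over admissible k of arrival - departure, its d-slope)."""
        arrive, d_arr = self._one_side(d)
        dep_ref, d_dep_ref = self._reflected()._one_side(d)
        depart = 1.0 - dep_ref[::-1]
        d_dep = -d_dep_ref[::-1]
        g = np.where(ok, arrive - depart, np.inf)
        k = int(np.argmin(g))
        return float(g[k]), float(d_arr[k] - d_dep[k])

    def _reflected(self):
        if not hasattr(self, "_refl"):
            self._refl = _ModeCoupling(
                -self.xv[::-1], (1.0 - self.upper)[::-1], (1.0 - self.lower)[::-1]
            )
        return self._refl


def dip_statistic(x) -> float:
    """Hartigan's dip: min over unimodal CDFs G of sup_x |F_n(x) - G(x)|.

    The mode may always be taken as an atom at one of the data values (a
    continuous mode is the zero-jump special case, and a mode outside the
    data range is dominated by an atom at the nearest extreme). For a mode
    at x_k the fit decomposes into a convex-minorant problem left of x_k and
    a concave-majorant problem right of it — each solvable in closed form
    from the hull of the ECDF staircase corners — plus a monotonicity
    coupling at the mode itself, resolved by a bracketed Newton iteration on
    its piecewise-linear, strictly decreasing gap.
    """
    xs = np.sort(np.asarray(x, dtype=float).ravel())
    n = xs.size
    if n < 4:
        raise ValueError("dip statistic needs at least 4 observations")
    vals, counts = np.unique(xs, return_counts=True)
    K = vals.size
    if K == 1:
        return 0.0
    cum = np.cumsum(counts)
    lower = (cum - counts) / n  # F(x_t-)
    upper = cum / n  # F(x_t)

    C = _left_deviation_profile(vals, lower, upper)
    # right side by reflection: x -> -x reverses order and swaps corner roles
    A = _left_deviation_profile(
        -vals[::-1], (1.0 - upper)[::-1], (1.0 - lower)[::-1]
    )[::-1]
    f = np.maximum(C, A)
    base = 0.5 * float(f.min())  # exact when the mode coupling is slack

    coup = _ModeCoupling(vals, lower, upper)
    tol = 1e-13

    def admissible(d):
        return f <= 2.0 * d + tol

    g0, _ = coup.gap(base, admissible(base))
    if g0 <= tol:
        return base

    # The gap is piecewise linear and decreasing in d within each stretch
    # where the admissible-mode set is constant, but jumps down whenever a
    # new mode knot crosses its max(C, A)/2 threshold — and the root very
    # often sits exactly at such a threshold. So: locate the bracketing pair
    # of thresholds by bisection on feasibility, then run Illinois false
    # position on the continuous piece in between.
    thresholds = np.unique(f[f > 2.0 * base + tol]) / 2.0
    lo, g_lo = base, g0
    hi, g_hi = None, None
    i, j = 0, len(thresholds)  # feasible somewhere <= thresholds[j]
    while i < j:
        mid = (i + j) // 2
        g, _ = coup.gap(thresholds[mid], admissible(thresholds[mid]))
        if g <= tol:
            j = mid
            hi, g_hi = thresholds[mid], g
        else:
            i = mid + 1
            lo, g_lo = thresholds[mid], g
    if hi is None:  # root beyond the last threshold: all modes admissible
        d_last = thresholds[-1] if len(thresholds) else base
        g_last, _ = coup.gap(d_last, np.ones(K, dtype=bool))
        lo, g_lo = d_last, g_last
        hi, g_hi = d_last + max(g_last, 0.0) / 2.0 + 1e-12, None
        g_hi, _ = coup.gap(hi, np.ones(K, dtype=bool))

    last = 0
    for _ in range(100):
        if hi - lo < 1e-14 or g_lo <= g_hi:
            break
        cand = lo + (hi - lo) * g_lo / (g_lo - g_hi)
        cand = min(max(cand, lo + 1e-17), hi - 1e-17)
        g, _ = coup.gap(cand, admissible(cand))
        if g > tol:
            lo, g_lo = cand, g
            if last == 1:
                g_hi *= 0.5
            last = 1
        else:
            hi, g_hi = cand, g
            if last == -1:
                g_lo *= 0.5
            last = -1
    return hi


def dip_test(x, n_boot: int = 2000, seed: int = 0) -> DipResult:
    """Dip statistic with a Monte Carlo p-value against the uniform null.

    The null reference is ``n_boot`` uniform samples of the same size; the
    p-value is (1 + #{null >= observed}) / (n_boot + 1).
    """
    x = np.asarray(x, dtype=float).ravel()
    stat = dip_statistic(x)
    rng = np.random.default_rng(seed)
    null = np.array(
        [dip_statistic(rng.uniform(size=x.size)) for _ in range(n_boot)]
    )
    p = (1.0 + np.sum(null >= stat)) / (n_boot + 1.0)
    return DipResult(statistic=stat, p_value=float(p), n=int(x.size))


# Cached null-dip reference tables on a log grid of sample sizes; p-values
# for intermediate n interpolate the empirical tail of sqrt(n)-scaled dips,
# the same device as published dip-test quantile tables.
_NULL_GRID = np.array(
    [4, 5, 6, 8, 10, 13, 16, 20, 25, 32, 40, 50, 64, 80, 100, 128, 160,
     200, 256, 320, 400, 500]
)
_NULL_TABLE_B = 1000
_null_tables: dict[int, np.ndarray] = {}


def _null_dips(n_grid: int) -> np.ndarray:
    if n_grid not in _null_tables:
        rng = np.random.default_rng(900_000 + n_grid)
        _null_tables[n_grid] = np.sort(
            [dip_statistic(rng.uniform(size=n_grid)) for _ in range(_NULL_TABLE_B)]
        )
    return _null_tables[n_grid]


def _tail_p(null_sorted: np.ndarray, x: float) -> float:
    """Empirical exceedance probability with an exponential tail extension.

    Inside the bulk this is the usual (1 + #{null >= x}) / (B + 1). Beyond
    the top decile the empirical estimate saturates at 1/(B+1), which would
    cap how small a p-value an overwhelmingly bimodal sample can earn (and
    with it the reach of step-down FWER control over many nodes); a
    peaks-over-threshold exponential fit to the top-decile exceedances
    extrapolates smoothly instead, floored at 1e-12.
    """
    b = len(null_sorted)
    cut = int(0.9 * b)
    u = null_sorted[cut]
    if x < u:
        k = int(np.searchsorted(null_sorted, x, side="left"))
        return (1.0 + b - k) / (b + 1.0)
    beta = float(np.mean(null_sorted[cut:] - u)) + 1e-12
    frac = (b - cut) / (b + 1.0)
    return float(max(frac * np.exp(-(x - u) / beta), 1e-12))


def dip_pvalue_table(stat: float, n: int) -> float:
    """Interpolated uniform-null p-value for a dip at sample size n."""
    if n >= _NULL_GRID[-1]:
        ns = [int(_NULL_GRID[-1])]
        wts = [1.0]
    else:
        hi = int(np.searchsorted(_NULL_GRID, n))
        if _NULL_GRID[hi] == n:
            ns, wts = [n], [1.0]
        else:
            n1, n2 = int(_NULL_GRID[hi - 1]), int(_NULL_GRID[hi])
            w2 = (np.log(n) - np.log(n1)) / (np.log(n2) - np.log(n1))
            ns, wts = [n1, n2], [1.0 - w2, w2]
    scaled = stat * np.sqrt(n)
    p = 0.0
    for ng, w in zip(ns, wts):
        null = _null_dips(ng) * np.sqrt(ng)
        p += w * _tail_p(null, scaled)
    return float(p)


# ---------------------------------------------------------------------------
# WSS-based estimators (Gap, Jump) and silhouette-based ones (Silhouette,
# Slope), plus the WCD elbow
# ---------------------------------------------------------------------------

def _as_matrix(prototypes) -> np.ndarray:
    return np.asarray(getattr(prototypes, "prototypes", prototypes), dtype=float)


def _tree_labels(tree: Dendrogram, k: int) -> np.ndarray:
    return cut_to_k(tree, k).labels


def _wss(x: np.ndarray, labels: np.ndarray) -> float:
    total = 0.0
    for lab in np.unique(labels):
        pts = x[labels == lab]
        total += float(((pts - pts.mean(axis=0)) ** 2).sum())
    return total


def _euclidean_tree(x: np.ndarray) -> Dendrogram:
    z = linkage(x, method="average", metric="euclidean")
    return Dendrogram(merges=z, leaf_ids=[str(i) for i in range(x.shape[0])])


def gap_statistic(
    prototypes, k_range=range(1, 11), B: int = 50, seed: int = 0
) -> KEstimate:
    """Gap statistic: observed log-WSS versus uniform reference data.

    Gap(k) = mean_b log W_k(ref_b) - log W_k(data) with references drawn
    uniformly over each feature's observed range; k_hat is the smallest k
    with Gap(k) >= Gap(k+1) - s_{k+1} (one-standard-error rule). Partitions
    come from cutting average-linkage trees.
    """
    x = _as_matrix(prototypes)
    ks = list(k_range)
    if B < 10:
        raise ValueError("need at least 10 reference sets")
    lo, hi = x.min(axis=0), x.max(axis=0)
    if np.any(hi - lo == 0):
        raise ValueError("a feature has zero range; cannot build uniform references")
    tree = _euclidean_tree(x)
    log_w = np.array([np.log(_wss(x, _tree_labels(tree, k)) + 1e-300) for k in ks])

    rng = np.random.default_rng(seed)
    ref_log_w = np.empty((B, len(ks)))
    for b in range(B):
        ref = rng.uniform(lo, hi, size=x.shape)
        rtree = _euclidean_tree(ref)
        ref_log_w[b] = [
            np.log(_wss(ref, _tree_labels(rtree, k)) + 1e-300) for k in ks
        ]
    gap = ref_log_w.mean(axis=0) - log_w
    s = ref_log_w.std(axis=0, ddof=0) * np.sqrt(1.0 + 1.0 / B)

    k_hat = ks[-1]
    for i in range(len(ks) - 1):
        if gap[i] >= gap[i + 1] - s[i + 1]:
            k_hat = ks[i]
            break
    return KEstimate(
        method="gap",
        k_hat=int(k_hat),
        curve=dict(zip(ks, gap.tolist())),
        details={"se": dict(zip(ks, s.tolist()))},
    )


def _silhouette_curve(d: DistanceMatrix, tree: Dendrogram, ks) -> np.ndarray:
    out = np.empty(len(ks))
    for i, k in enumerate(ks):
        labels = _tree_labels(tree, k)
        out[i] = silhouette_score(d.values, labels, metric="precomputed")
    return out


def silhouette_statistic(d: DistanceMatrix, k_range=range(2, 11)) -> KEstimate:
    """Mean silhouette width per tree cut; k_hat is the argmax (ties -> smallest k)."""
    ks = list(k_range)
    tree = hierarchical_average(d)
    curve = _silhouette_curve(d, tree, ks)
    return KEstimate(
        method="silhouette",
        k_hat=int(ks[int(np.argmax(curve))]),
        curve=dict(zip(ks, curve.tolist())),
    )


def jump_statistic(prototypes, k_range=range(1, 11), power: float | None = None) -> KEstimate:
    """Jump statistic on transformed distortion d_k = W_k / (P*M).

    J_k = d_k^(-Y) - d_{k-1}^(-Y) with d_0^(-Y) = 0 and default power
    Y = M/2; k_hat is the argmax of J. Duplicate prototypes that zero out a
    W_k are floored at machine epsilon.
    """
    x = _as_matrix(prototypes)
    p, m = x.shape
    y = m / 2.0 if power is None else float(power)
    if y <= 0:
        raise ValueError("power must be positive")
    ks = list(k_range)
    tree = _euclidean_tree(x)
    prev = [ks[0] - 1] if ks[0] > 1 else []
    all_k = prev + ks
    w = {}
    w_last = np.inf
    for k in all_k:
        wk = _wss(x, _tree_labels(tree, k)) if k >= 1 else np.inf
        if wk <= 0:
            wk = np.finfo(float).tiny
        # monotonicity guard: nested tree cuts keep WSS nonincreasing in k
        w[k] = min(wk, w_last)
        w_last = w[k]
    d = {k: w[k] / (p * m) for k in all_k}
    j = []
    for i, k in enumerate(ks):
        d_prev = 0.0 if k == 1 else d[all_k[all_k.index(k) - 1]] ** (-y)
        j.append(d[k] ** (-y) - d_prev)
    j = np.asarray(j)
    return KEstimate(
        method="jump", k_hat=int(ks[int(np.argmax(j))]), curve=dict(zip(ks, j.tolist()))
    )


def slope_statistic(d: DistanceMatrix, k_range=range(2, 11), v: float = 1.0) -> KEstimate:
    """Slope statistic: -(s(k+1) - s(k)) * s(k)^v on the silhouette curve.

    The curve has one fewer entry than k_range; k_hat is the argmax.
    """
    if v <= 0:
        raise ValueError("exponent v must be positive")
    ks = list(k_range)
    tree = hierarchical_average(d)
    s = _silhouette_curve(d, tree, ks)
    slope = -(s[1:] - s[:-1]) * np.sign(s[:-1]) * np.abs(s[:-1]) ** v
    return KEstimate(
        method="slope",
        k_hat=int(ks[int(np.argmax(slope))]),
        curve=dict(zip(ks[:-1], slope.tolist())),
    )


def wcd_elbow(prototypes, k_range=range(2, 11)) -> KEstimate:
    """Mean within-cluster distance per k; k_hat at the greatest-curvature elbow.

    The elbow is the interior k maximizing the discrete second difference of
    the curve; a flat (no-elbow) curve falls back to the smallest interior k.
    """
    x = _as_matrix(prototypes)
    ks = list(k_range)
    if len(ks) < 3:
        raise ValueError("k_range must span at least 3 values")
    tree = _euclidean_tree(x)
    d = pairwise_distance(x, "euclidean").values
    curve = np.empty(len(ks))
    for i, k in enumerate(ks):
        labels = _tree_labels(tree, k)
        acc, cnt = 0.0, 0
        for lab in np.unique(labels):
            idx = np.where(labels == lab)[0]
            if idx.size > 1:
                sub = d[np.ix_(idx, idx)]
                acc += sub[np.triu_indices(idx.size, k=1)].sum()
                cnt += idx.size * (idx.size - 1) // 2
        curve[i] = acc / cnt if cnt else 0.0
    second = curve[:-2] - 2.0 * curve[1:-1] + curve[2:]
    k_hat = ks[1 + int(np.argmax(second))]
    return KEstimate(method="wcd", k_hat=int(k_hat), curve=dict(zip(ks, curve.tolist())))


# ---------------------------------------------------------------------------
# Discriminant method: projection pursuit + dip test on the dendrogram
# ---------------------------------------------------------------------------

def max_clusterability_projection(points: np.ndarray, split: np.ndarray) -> np.ndarray:
    """Project points onto the two-class discriminant direction.

    The direction maximizes between-class separation over within-class
    scatter, i.e. w ∝ S_w^{-1} (mu_1 - mu_2), with the within-class scatter
    ridge-regularized by a trace-scaled identity so degenerate classes still
    produce a direction.
    """
    x = np.asarray(points, dtype=float)
    split = np.asarray(split)
    classes = np.unique(split)
    if classes.size != 2:
        raise ValueError("split must define exactly two classes")
    a, b = x[split == classes[0]], x[split == classes[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both classes need at least 2 members")
    m = x.shape[1]
    sw = np.cov(a, rowvar=False) * (len(a) - 1) + np.cov(b, rowvar=False) * (len(b) - 1)
    ridge = 1e-6 * (np.trace(sw) / m + 1.0)
    w = np.linalg.solve(sw + ridge * np.eye(m), a.mean(axis=0) - b.mean(axis=0))
    norm = np.linalg.norm(w)
    if norm == 0:  # identical class means: any direction is as good as another
        w = np.zeros(m)
        w[0] = 1.0
    else:
        w = w / norm
    return x @ w


def _holm(pvalues: np.ndarray, alpha: float) -> np.ndarray:
    """Holm step-down: boolean mask of rejected hypotheses at FWER alpha."""
    m = len(pvalues)
    order = np.argsort(pvalues)
    reject = np.zeros(m, dtype=bool)
    for rank, idx in enumerate(order):
        if pvalues[idx] <= alpha / (m - rank):
            reject[idx] = True
        else:
            break
    return reject


def _bonferroni(pvalues: np.ndarray, alpha: float) -> np.ndarray:
    return pvalues <= alpha / len(pvalues)


def _node_members(z: np.ndarray):
    """Leaf sets of every internal node of a linkage matrix, in merge order."""
    p = z.shape[0] + 1
    members = {i: [i] for i in range(p)}
    out = []
    for i in range(z.shape[0]):
        left, right = int(z[i, 0]), int(z[i, 1])
        members[p + i] = members[left] + members[right]
        out.append((members[left], members[right]))
    return out


def discriminant_k(
    prototypes,
    alpha: float = 0.05,
    min_node_size: int = 10,
    seed: int = 0,
    fwer: str = "holm",
    use_table: bool = True,
    n_boot: int = 2000,
    max_dip_n: int = 200,
) -> KEstimate:
    """Estimate k by dip-testing discriminant projections at dendrogram nodes.

    For every internal node of the average-linkage tree whose two children
    jointly hold at least ``min_node_size`` points (each child >= 2), the
    node's points are projected onto the children's discriminant direction
    and Hartigan's dip test is applied to the projections (a seeded
    subsample of at most ``max_dip_n`` projections at very large nodes —
    the test remains exact under exchangeability and keeps node cost
    bounded). Node p-values are FWER-adjusted (Holm by default, Bonferroni
    available); s significant splits imply s + 1 groups, floored at 1.
    """
    x = _as_matrix(prototypes)
    if x.shape[0] < 8:
        raise ValueError("need at least 8 prototypes")
    if fwer not in ("holm", "bonferroni"):
        raise ValueError("fwer must be 'holm' or 'bonferroni'")
    tree = _euclidean_tree(x)
    nodes = []
    for left, right in _node_members(tree.merges):
        if len(left) >= 2 and len(right) >= 2 and len(left) + len(right) >= min_node_size:
            nodes.append((left, right))

    pvals, stats, sizes = [], [], []
    rng = np.random.default_rng(seed)
    for left, right in nodes:
        idx = np.array(left + right)
        split = np.r_[np.zeros(len(left), dtype=int), np.ones(len(right), dtype=int)]
        proj = max_clusterability_projection(x[idx], split)
        if proj.size > max_dip_n:
            proj = rng.choice(proj, size=max_dip_n, replace=False)
        stat = dip_statistic(proj)
        if use_table:
            p = dip_pvalue_table(stat, proj.size)
        else:
            p = dip_test(proj, n_boot=n_boot, seed=int(rng.integers(2**31))).p_value
        pvals.append(p)
        stats.append(stat)
        sizes.append(proj.size)

    if pvals:
        adjust = _holm if fwer == "holm" else _bonferroni
        reject = adjust(np.asarray(pvals), alpha)
        n_sig = int(reject.sum())
    else:
        n_sig = 0
    return KEstimate(
        method="discriminant",
        k_hat=max(n_sig + 1, 1),
        curve={},
        alpha=alpha,
        details={"p_values": pvals, "dip": stats, "node_sizes": sizes},
    )


ESTIMATORS = ("gap", "silhouette", "jump", "slope", "wcd", "discriminant")


def estimate_k(
    prototypes,
    method: str,
    k_range=range(2, 11),
    seed: int = 0,
    metric: str = "euclidean",
    alpha: float = 0.05,
) -> KEstimate:
    """Dispatch to one of the six estimators with sensible defaults."""
    x = _as_matrix(prototypes)
    if method == "gap":
        return gap_statistic(x, k_range=range(1, max(k_range) + 1), seed=seed)
    if method == "jump":
        return jump_statistic(x, k_range=range(1, max(k_range) + 1))
    if method == "silhouette":
        return silhouette_statistic(pairwise_distance(x, metric), k_range=k_range)
    if method == "slope":
        return slope_statistic(pairwise_distance(x, metric), k_range=k_range)
    if method == "wcd":
        return wcd_elbow(x, k_range=k_range)
    if method == "discriminant":
        return discriminant_k(x, alpha=alpha, seed=seed)
    raise ValueError(f"unknown estimator {method!r}; choose from {ESTIMATORS}")
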