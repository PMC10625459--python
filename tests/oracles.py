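"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive — double loops, exhaustive pair
enumeration, O(P^3) agglomeration, linear programming — and never shares
code with the package implementation it checks.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linprog


# --- pairwise metrics: naive double loop over rows ------------------------

def naive_pairwise(x: np.ndarray, metric: str) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    n, m = x.shape
    out = np.zeros((n, n))

    def rank(v):
        order = np.argsort(v, kind="mergesort")
        r = np.empty(m)
        i = 0
        sv = v[order]
        while i < m:
            j = i
            while j + 1 < m and sv[j + 1] == sv[i]:
                j += 1
            r[order[i : j + 1]] = (i + j) / 2.0 + 1.0
            i = j + 1
        return r

    for i in range(n):
        for j in range(i + 1, n):
            a, b = x[i], x[j]
            if metric == "euclidean":
                d = np.sqrt(np.sum((a - b) ** 2))
            elif metric == "manhattan":
                d = np.sum(np.abs(a - b))
            elif metric == "maximum":
                d = np.max(np.abs(a - b))
            else:
                if metric == "spearman":
                    a, b = rank(a), rank(b)
                if metric in ("pearson", "spearman"):
                    ac, bc = a - a.mean(), b - b.mean()
                    r = np.sum(ac * bc) / np.sqrt(np.sum(ac**2) * np.sum(bc**2))
                else:  # cosine
                    r = np.sum(a * b) / np.sqrt(np.sum(a**2) * np.sum(b**2))
                r = min(1.0, max(-1.0, r))
                d = np.sqrt(2.0 * (1.0 - r))
            out[i, j] = out[j, i] = d
    return out


# --- evaluation indices: exhaustive pair enumeration and direct entropies ---

def enumerate_pairs(x, y):
    x, y = np.asarray(x), np.asarray(y)
    tp = fp = fn = tn = 0
    n = len(x)
    for i in range(n):
        for j in range(i + 1, n):
            same_x = x[i] == x[j]
            same_y = y[i] == y[j]
            tp += same_x and same_y
            fp += same_x and not same_y
            fn += same_y and not same_x
            tn += not same_x and not same_y
    return tp, fp, fn, tn


def naive_ari(x, y):
    tp, fp, fn, tn = enumerate_pairs(x, y)
    total = tp + fp + fn + tn
    sum_a = tp + fp
    sum_b = tp + fn
    expected = sum_a * sum_b / total
    max_index = (sum_a + sum_b) / 2.0
    if max_index - expected == 0:
        ident = sum(1 for i in range(len(x)) for j in range(len(x)) if (
            (np.asarray(x)[i] == np.asarray(x)[j]) != (np.asarray(y)[i] == np.asarray(y)[j])
        )) == 0
        return 1.0 if ident else 0.0
    return (tp - expected) / (max_index - expected)


def naive_nmi(x, y):
    x, y = np.asarray(x), np.asarray(y)
    n = len(x)

    def entropy(labels):
        h = 0.0
        for v in set(labels.tolist()):
            p = np.mean(labels == v)
            h -= p * np.log(p)
        return h

    hx, hy = entropy(x), entropy(y)
    if hx + hy == 0:
        return 1.0
    mi = 0.0
    for a in set(x.tolist()):
        for b in set(y.tolist()):
            pab = np.mean((x == a) & (y == b))
            if pab > 0:
                mi += pab * np.log(pab / (np.mean(x == a) * np.mean(y == b)))
    return 2.0 * max(mi, 0.0) / (hx + hy)


def naive_fm(x, y):
    tp, fp, fn, _ = enumerate_pairs(x, y)
    if tp == 0:
        return 0.0
    return tp / np.sqrt((tp + fp) * (tp + fn))


def naive_f(x, y):
    tp, fp, fn, _ = enumerate_pairs(x, y)
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    return 2 * p * r / (p + r) if p + r else 0.0


# --- UPGMA: O(P^3) matrix-shrinking agglomeration ---------------------------

def naive_upgma_heights(d: np.ndarray) -> np.ndarray:
    """Merge heights of average-linkage clustering, smallest-pair-first."""
    d = np.asarray(d, dtype=float).copy()
    n = d.shape[0]
    active = list(range(n))
    sizes = {i: 1 for i in range(n)}
    dd = {(i, j): d[i, j] for i in range(n) for j in range(i + 1, n)}
    heights = []
    nxt = n
    while len(active) > 1:
        best = None
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                i, j = active[ai], active[aj]
                key = (min(i, j), max(i, j))
                if best is None or dd[key] < best[0] - 1e-15:
                    best = (dd[key], i, j)
        h, i, j = best
        heights.append(h)
        si, sj = sizes[i], sizes[j]
        for k in active:
            if k in (i, j):
                continue
            dik = dd[(min(i, k), max(i, k))]
            djk = dd[(min(j, k), max(j, k))]
            dd[(min(nxt, k), max(nxt, k))] = (si * dik + sj * djk) / (si + sj)
        active = [a for a in active if a not in (i, j)] + [nxt]
        sizes[nxt] = si + sj
        nxt += 1
    return np.asarray(heights)


# --- Hartigan dip: LP over explicit unimodal-CDF parameterizations ----------

def lp_dip(sample) -> float:
    """Exact dip via linear programs, one per mode placement.

    For every placement of the mode (an atom at a distinct data value, or
    inside a gap between values) the best unimodal CDF is piecewise linear
    with knots at the data; finding it is an LP in the knot values and the
    sup-distance d. Only practical for small n.
    """
    xs = np.sort(np.asarray(sample, float))
    n = xs.size
    vals, counts = np.unique(xs, return_counts=True)
    K = len(vals)
    if K == 1:
        return 0.0
    cum = np.cumsum(counts)
    lower = (cum - counts) / n
    upper = cum / n
    dx = np.diff(vals)

    best = np.inf

    def solve(rows, rhs, nvar):
        c = np.zeros(nvar)
        c[-1] = 1.0
        res = linprog(
            c,
            A_ub=np.array(rows),
            b_ub=np.array(rhs),
            bounds=[(0.0, 1.0)] * (nvar - 1) + [(0, None)],
            method="highs",
        )
        return res.fun if res.status == 0 else np.inf

    # mode = atom at knot k: left values L_0..L_k (L_k the left limit),
    # right values R_k..R_{K-1} (R_k the CDF value at the mode)
    for k in range(K):
        nL = k + 1
        nvar = nL + (K - k) + 1
        D = nvar - 1
        rows, rhs = [], []

        def vl(t):
            return t

        def vr(t, nL=nL, k=k):
            return nL + (t - k)

        for t in range(k):
            r = np.zeros(nvar); r[vl(t)] = -1; r[D] = -1
            rows.append(r); rhs.append(-upper[t])
            r = np.zeros(nvar); r[vl(t)] = 1; r[D] = -1
            rows.append(r); rhs.append(lower[t])
        for bound, sign in ((lower[k], -1), (lower[k], 1)):
            r = np.zeros(nvar); r[vl(k)] = sign; r[D] = -1
            rows.append(r); rhs.append(sign * bound)
        for bound, sign in ((upper[k], -1), (upper[k], 1)):
            r = np.zeros(nvar); r[vr(k)] = sign; r[D] = -1
            rows.append(r); rhs.append(sign * bound)
        for t in range(k + 1, K):
            r = np.zeros(nvar); r[vr(t)] = -1; r[D] = -1
            rows.append(r); rhs.append(-upper[t])
            r = np.zeros(nvar); r[vr(t)] = 1; r[D] = -1
            rows.append(r); rhs.append(lower[t])
        # monotone across the jump and along both sides
        r = np.zeros(nvar); r[vl(k)] = 1; r[vr(k)] = -1
        rows.append(r); rhs.append(0.0)
        for t in range(k):
            r = np.zeros(nvar); r[vl(t)] = 1; r[vl(t + 1)] = -1
            rows.append(r); rhs.append(0.0)
        for t in range(k, K - 1):
            r = np.zeros(nvar); r[vr(t)] = 1; r[vr(t + 1)] = -1
            rows.append(r); rhs.append(0.0)
        # convex slopes left, concave slopes right
        for t in range(k - 1):
            r = np.zeros(nvar)
            r[vl(t)] += -1 / dx[t]
            r[vl(t + 1)] += 1 / dx[t] + 1 / dx[t + 1]
            r[vl(t + 2)] += -1 / dx[t + 1]
            rows.append(r); rhs.append(0.0)
        for t in range(k, K - 2):
            r = np.zeros(nvar)
            r[vr(t)] += 1 / dx[t]
            r[vr(t + 1)] += -1 / dx[t] - 1 / dx[t + 1]
            r[vr(t + 2)] += 1 / dx[t + 1]
            rows.append(r); rhs.append(0.0)
        best = min(best, solve(rows, rhs, nvar))

    # continuous mode inside segment k (k = -1: all concave; K-1: all convex)
    for k in range(-1, K):
        nvar = K + 1
        D = K
        rows, rhs = [], []
        for t in range(K):
            r = np.zeros(nvar); r[t] = -1; r[D] = -1
            rows.append(r); rhs.append(-upper[t])
            r = np.zeros(nvar); r[t] = 1; r[D] = -1
            rows.append(r); rhs.append(lower[t])
        for t in range(K - 1):
            r = np.zeros(nvar); r[t] = 1; r[t + 1] = -1
            rows.append(r); rhs.append(0.0)
        for t in range(K - 2):
            r = np.zeros(nvar)
            if t + 1 <= k:  # convex region
                r[t] += -1 / dx[t]
                r[t + 1] += 1 / dx[t] + 1 / dx[t + 1]
                r[t + 2] += -1 / dx[t + 1]
            else:  # concave region
                r[t] += 1 / dx[t]
                r[t + 1] += -1 / dx[t] - 1 / dx[t + 1]
                r[t + 2] += 1 / dx[t + 1]
            rows.append(r); rhs.append(0.0)
        best = min(best, solve(rows, rhs, nvar))
    return best
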