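"""Brute-force dip oracle: exhaustive minimisation over unimodal CDFs.

Independent of the production implementation: for every candidate modal
position (strictly between adjacent sample points, outside the sample
range, or an atom at a sample point) it solves a small linear program
for the minimal sup-norm band half-width t admitting a monotone CDF that
is convex left of the mode and concave right of it through the ECDF's
step corridor; the dip is the minimum over modal positions.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linprog


def _solve_mode(v, before, after, n, mode_kind, k):
    """Min t for one modal hypothesis.

    mode_kind 'between': mode in (v[k-1], v[k]) — convex over points <k,
    concave over points >=k (k may be 0 or K).
    mode_kind 'at': atom at v[k] — the CDF may jump there; its left limit
    a and value b are separate variables.
    """
    K = v.size
    extra = 2 if mode_kind == "at" else 0
    nv = K + extra + 1  # g_0..g_{K-1} (+a, b) and t
    ti = nv - 1
    c = np.zeros(nv)
    c[ti] = 1.0
    A_ub, b_ub = [], []

    def band(var, low_cnt, up_cnt):
        # low_cnt/n - t <= g_var <= up_cnt/n + t
        row = np.zeros(nv)
        row[var] = -1.0
        row[ti] = -1.0
        A_ub.append(row)
        b_ub.append(-low_cnt / n)
        row = np.zeros(nv)
        row[var] = 1.0
        row[ti] = -1.0
        A_ub.append(row)
        b_ub.append(up_cnt / n)

    if mode_kind == "between":
        for i in range(K):
            band(i, after[i], before[i])
        convex_pts = list(range(k))  # indices strictly left of the mode
        concave_pts = list(range(k, K))
        chain = list(range(K))
    else:
        # variables: g_i for i != k use slot i; a -> slot K, b -> slot K+1
        for i in range(K):
            if i != k:
                band(i, after[i], before[i])
        band(K, before[k], before[k])  # |a - before_k/n| <= t
        band(K + 1, after[k], after[k])  # |b - after_k/n| <= t
        convex_pts = list(range(k)) + ["a"]
        concave_pts = ["b"] + list(range(k + 1, K))
        chain = list(range(k)) + ["a", "b"] + list(range(k + 1, K))

    def slot(p):
        if p == "a":
            return K
        if p == "b":
            return K + 1
        return p

    def xof(p):
        if p in ("a", "b"):
            return v[k]
        return v[p]

    # monotone along the chain
    for p, q in zip(chain, chain[1:]):
        row = np.zeros(nv)
        row[slot(p)] = 1.0
        row[slot(q)] = -1.0
        A_ub.append(row)
        b_ub.append(0.0)

    def curvature(pts, sign):
        # sign=+1 convex: slopes nondecreasing; -1 concave
        for p, q, r in zip(pts, pts[1:], pts[2:]):
            x1, x2, x3 = xof(p), xof(q), xof(r)
            if x3 == x1:
                continue
            lam = (x2 - x1) / (x3 - x1)
            # convex: g_q <= (1-lam) g_p + lam g_r
            row = np.zeros(nv)
            row[slot(q)] += sign
            row[slot(p)] -= sign * (1 - lam)
            row[slot(r)] -= sign * lam
            A_ub.append(row)
            b_ub.append(0.0)

    curvature(convex_pts, +1.0)
    curvature(concave_pts, -1.0)

    bounds = [(0.0, 1.0)] * (nv - 1) + [(0.0, 0.5)]
    res = linprog(c, A_ub=np.array(A_ub), b_ub=np.array(b_ub), bounds=bounds, method="highs")
    if not res.success:
        return np.inf
    return float(res.x[ti])


def dip_bruteforce(values) -> float:
    """Exhaustive-minimisation dip of a small sample (use n <= ~20)."""
    x = np.sort(np.asarray(values, dtype=float).ravel())
    n = x.size
    if n < 2:
        raise ValueError("need n >= 2")
    v, counts = np.unique(x, return_counts=True)
    K = v.size
    if K < 2:
        raise ValueError("need >= 2 distinct values")
    after = np.cumsum(counts).astype(float)
    before = after - counts
    best = np.inf
    for k in range(K + 1):
        best = min(best, _solve_mode(v, before, after, n, "between", k))
    for k in range(K):
        best = min(best, _solve_mode(v, before, after, n, "at", k))
    return max(best, 1.0 / (2.0 * n))
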