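"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (enumeration, closed forms, textbook
recursions) and shares no code with the package implementation paths it
checks.
"""

from __future__ import annotations

import itertools
import math
from functools import lru_cache

import numpy as np

BASES = "ACGT"


# ---------------------------------------------------------------------------
# Scanning / score p-values


def brute_force_scan(residues, table, rc_table, threshold_score):
    """All (offset, strand, score) with score >= threshold, by direct loops."""
    w = table.shape[0]
    idx = {c: i for i, c in enumerate(BASES)}
    hits = []
    for off in range(len(residues) - w + 1):
        word = residues[off : off + w].upper()
        if "N" in word:
            continue
        for strand, tab in (("+", table), ("-", rc_table)):
            s = sum(tab[j, idx[word[j]]] for j in range(w))
            if s >= threshold_score - 1e-6:
                hits.append((off, strand, s))
    return hits


def enumerate_score_pvalue(table, background, score):
    """P(S >= score) by summing background probabilities of all 4^w words."""
    w = table.shape[0]
    total = 0.0
    for word in itertools.product(range(4), repeat=w):
        s = sum(table[j, b] for j, b in enumerate(word))
        if s >= score - 1e-6:
            p = 1.0
            for b in word:
                p *= background[b]
            total += p
    return total


# ---------------------------------------------------------------------------
# Statistics


def hypergeom_fisher_greater(a, b, c, d):
    """One-sided (enrichment) Fisher p for [[a, b], [c, d]] by enumerating
    tables with the same margins and first cell >= a."""
    row1, col1, n = a + b, a + c, a + b + c + d

    def pmf(x):
        return (
            math.comb(col1, x)
            * math.comb(n - col1, row1 - x)
            / math.comb(n, row1)
        )

    hi = min(row1, col1)
    return sum(pmf(x) for x in range(a, hi + 1))


def bh_stepup(p_values):
    """Benjamini-Hochberg by the explicit step-up formula."""
    p = np.asarray(p_values, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running = 1.0
    for rank_from_end, i in enumerate(order[::-1]):
        rank = m - rank_from_end
        running = min(running, p[i] * m / rank)
        adjusted[i] = running
    return adjusted


def signed_rank_exact_p(diffs):
    """Two-sided exact Wilcoxon signed-rank p by enumerating all 2^n sign
    assignments (no-ties input assumed); p = 2*min(P(W+<=w), P(W+>=w)), capped."""
    d = np.asarray(diffs, float)
    d = d[d != 0]
    n = d.size
    ranks = np.argsort(np.argsort(np.abs(d))) + 1
    w_obs = float(ranks[d > 0].sum())
    ws = []
    for signs in itertools.product([0, 1], repeat=n):
        ws.append(float(sum(r for r, s in zip(ranks, signs) if s)))
    ws = np.array(ws)
    p_le = np.mean(ws <= w_obs + 1e-9)
    p_ge = np.mean(ws >= w_obs - 1e-9)
    return min(1.0, 2 * min(p_le, p_ge))


def exact_binom_upper_tail(k, n, p0):
    """P(X >= k) for X ~ Bin(n, p0) by direct summation."""
    return sum(
        math.comb(n, j) * p0**j * (1 - p0) ** (n - j) for j in range(k, n + 1)
    )


# ---------------------------------------------------------------------------
# Alignment (affine gaps, lexicographic (score, matches, -columns) optimum)

MATCH, MISMATCH, OPEN, EXTEND = 1, -1, 5, 1


def align_oracle(a: str, b: str):
    """Memoized top-down recursion over (i, j, state); returns the optimal
    (score, matches, -columns) tuple for a global alignment."""

    @lru_cache(maxsize=None)
    def best(i, j, state):
        # state: 0 = can do anything, 1 = in gap consuming a, 2 = in gap consuming b
        if i == len(a) and j == len(b):
            return (0, 0, 0)
        options = []
        if i < len(a) and j < len(b):
            eq = a[i].upper() == b[j].upper()
            s, m, c = best(i + 1, j + 1, 0)
            options.append((s + (MATCH if eq else MISMATCH), m + (1 if eq else 0), c - 1))
        if i < len(a):
            s, m, c = best(i + 1, j, 1)
            cost = EXTEND if state == 1 else OPEN
            options.append((s - cost, m, c - 1))
        if j < len(b):
            s, m, c = best(i, j + 1, 2)
            cost = EXTEND if state == 2 else OPEN
            options.append((s - cost, m, c - 1))
        return max(options)

    return best(0, 0, 0)


# ---------------------------------------------------------------------------
# Clustering (Lance-Williams agglomeration)


def lance_williams_heights(dist, method):
    """Naive O(n^3) agglomeration; returns sorted merge heights.

    average: d(k, ij) = (ni d(ki) + nj d(kj)) / (ni + nj)
    ward (on distances as given):
        d(k, ij) = sqrt(((nk+ni) d(ki)^2 + (nk+nj) d(kj)^2 - nk d(ij)^2)
                        / (nk+ni+nj))
    """
    d = {(i, j): dist[i][j] for i in range(len(dist)) for j in range(len(dist)) if i != j}
    sizes = {i: 1 for i in range(len(dist))}
    active = set(sizes)
    heights = []
    next_id = len(dist)
    while len(active) > 1:
        i, j = min(
            ((i, j) for i in active for j in active if i < j),
            key=lambda ij: (d[ij], ij),
        )
        h = d[(i, j)]
        heights.append(h)
        ni, nj = sizes[i], sizes[j]
        for k in active - {i, j}:
            dki, dkj = d[(min(i, k), max(i, k))], d[(min(j, k), max(j, k))]
            if method == "average":
                new = (ni * dki + nj * dkj) / (ni + nj)
            else:
                nk = sizes[k]
                new = math.sqrt(
                    max(
                        0.0,
                        ((nk + ni) * dki**2 + (nk + nj) * dkj**2 - nk * h**2)
                        / (nk + ni + nj),
                    )
                )
            d[(min(k, next_id), max(k, next_id))] = new
        active -= {i, j}
        active.add(next_id)
        sizes[next_id] = ni + nj
        next_id += 1
    return sorted(heights)


# ---------------------------------------------------------------------------
# Union-find (interval clustering)


def union_find_clusters(intervals):
    """Transitive closure of pairwise overlap via a plain union-find."""
    parent = list(range(len(intervals)))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(len(intervals)):
        for j in range(i + 1, len(intervals)):
            (c1, s1, e1), (c2, s2, e2) = intervals[i], intervals[j]
            if c1 == c2 and s1 < e2 and s2 < e1:
                parent[find(i)] = find(j)
    clusters = {}
    for i in range(len(intervals)):
        clusters.setdefault(find(i), set()).add(i)
    return sorted(frozenset(v) for v in clusters.values())


# ---------------------------------------------------------------------------
# SVM primal via the dual QP


def svm_qp_oracle(X, y, costs):
    """Solve the soft-margin linear-SVM dual with SLSQP and recover (w, b).

    maximize  sum(alpha) - 1/2 sum_ij alpha_i alpha_j y_i y_j <x_i, x_j>
    s.t.      0 <= alpha_i <= C_i,   sum_i alpha_i y_i = 0
    """
    from scipy.optimize import minimize

    X = np.asarray(X, float)
    y = np.asarray(y, float)
    costs = np.asarray(costs, float)
    K = (X @ X.T) * np.outer(y, y)

    def neg_dual(alpha):
        return -(alpha.sum() - 0.5 * alpha @ K @ alpha)

    def neg_dual_grad(alpha):
        return -(np.ones_like(alpha) - K @ alpha)

    n = X.shape[0]
    res = minimize(
        neg_dual,
        x0=np.zeros(n),
        jac=neg_dual_grad,
        bounds=[(0, c) for c in costs],
        constraints=[{"type": "eq", "fun": lambda a: a @ y, "jac": lambda a: y}],
        method="SLSQP",
        options={"maxiter": 2000, "ftol": 1e-14},
    )
    alpha = res.x
    w = (alpha * y) @ X
    on_margin = (alpha > 1e-6 * costs.max()) & (alpha < costs - 1e-6 * costs.max())
    if on_margin.any():
        b = float(np.mean(y[on_margin] - X[on_margin] @ w))
    else:
        sv = alpha > 1e-8
        b = float(np.mean(y[sv] - X[sv] @ w))
    return w, b
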