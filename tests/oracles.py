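"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the library's vectorized code paths: plain loops,
explicit formulas, and exhaustive enumeration, so that agreement with the
package is a real cross-check.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np


def naive_ataxic(values: np.ndarray) -> tuple[np.ndarray, list[int]]:
    """Two-loop scorer: per-gene z-scores, then per-cell SD of |z|.

    Returns (scores per cell, indices of dropped zero-variance genes).
    """
    m, t = values.shape
    z_rows = []
    dropped = []
    for i in range(m):
        row = values[i]
        mean = sum(row) / t
        ss = sum((v - mean) ** 2 for v in row)
        sd = math.sqrt(ss / (t - 1))
        if sd == 0:
            dropped.append(i)
            continue
        z_rows.append([(v - mean) / sd for v in row])
    mprime = len(z_rows)
    scores = []
    for j in range(t):
        col = [abs(z_rows[i][j]) for i in range(mprime)]
        mean = sum(col) / mprime
        ss = sum((v - mean) ** 2 for v in col)
        scores.append(math.sqrt(ss / (mprime - 1)))
    return np.array(scores), dropped


def bh_brute(p: np.ndarray) -> np.ndarray:
    """Step-up adjustment straight from the definition.

    adj(i) = min over k with p(k) >= p(i) in sorted order of p(k) * m / rank(k),
    capped at 1, returned in input order.
    """
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    adj_sorted = np.empty(m)
    for i in range(m):
        adj_sorted[i] = min(
            min(sorted_p[k] * m / (k + 1) for k in range(i, m)), 1.0
        )
    out = np.empty(m)
    out[order] = adj_sorted
    return out


def mann_whitney_enum_p(a, b, direction: str) -> float:
    """Exact one-tailed p by enumerating all assignments of ranks to group a.

    Valid only without ties.  Under the null every subset of positions in the
    pooled ordering is equally likely to belong to group a.
    """
    a = list(map(float, a))
    b = list(map(float, b))
    pooled = sorted(a + b)
    assert len(set(pooled)) == len(pooled), "enumeration oracle requires no ties"

    def u_of(a_vals, b_vals):
        return sum(1 for x in a_vals for y in b_vals if x > y)

    u_obs = u_of(a, b)
    n = len(pooled)
    na = len(a)
    total = 0
    extreme = 0
    for idx in combinations(range(n), na):
        a_vals = [pooled[i] for i in idx]
        b_vals = [pooled[i] for i in range(n) if i not in idx]
        u = u_of(a_vals, b_vals)
        total += 1
        if direction == "a_greater":
            extreme += u >= u_obs
        else:
            extreme += u <= u_obs
    return extreme / total


def rank_average(x) -> list[float]:
    """Average ranks computed by explicit grouping of tied values."""
    x = list(map(float, x))
    order = sorted(range(len(x)), key=lambda i: x[i])
    ranks = [0.0] * len(x)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and x[order[j + 1]] == x[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def spearman_rank_pearson(x, y) -> float:
    """Spearman rho as Pearson correlation of average ranks, by hand."""
    rx = rank_average(x)
    ry = rank_average(y)
    n = len(rx)
    mx = sum(rx) / n
    my = sum(ry) / n
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(
        sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry)
    )
    return num / den
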