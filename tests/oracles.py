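"""Independent brute-force oracles used only by the test suite.

Each oracle is deliberately implemented on a different path from the
package code it checks: recursive-with-memo edit distance instead of the
iterative DP table, per-pair scalar loops instead of vectorized matrices,
and explicit set comparisons for the approximations.
"""

from __future__ import annotations

import sys
from functools import lru_cache

import numpy as np

from anrs import HybridTable
from anrs.distance import DistanceParams, hybrid_distance


def lev_recursive(a: str, b: str) -> int:
    """Plain recursive definition of edit distance (memoized)."""

    @lru_cache(maxsize=None)
    def rec(i: int, j: int) -> int:
        if i == 0:
            return j
        if j == 0:
            return i
        return min(
            rec(i - 1, j) + 1,
            rec(i, j - 1) + 1,
            rec(i - 1, j - 1) + (a[i - 1] != b[j - 1]),
        )

    sys.setrecursionlimit(10000)
    return rec(len(a), len(b))


def brute_distances(table: HybridTable, params: DistanceParams) -> np.ndarray:
    """All-pairs distances via the scalar two-record function."""
    n = len(table)
    recs = table.records()
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            out[i, j] = hybrid_distance(recs[i], recs[j], params)
    return out


def brute_approximations(table: HybridTable, params: DistanceParams, r: float):
    """Enumerate every granule and compare sets explicitly."""
    dmat = brute_distances(table, params)
    labels = list(table.labels)
    n = len(table)
    classes = sorted(set(labels))
    granules = []
    for i in range(n):
        row = dmat[i]
        delta = row.min() + r * (row.max() - row.min())
        granules.append({j for j in range(n) if row[j] <= delta})
    lower = {c: set() for c in classes}
    upper = {c: set() for c in classes}
    for c in classes:
        members = {j for j in range(n) if labels[j] == c}
        for i in range(n):
            if granules[i] <= members:
                lower[c].add(i)
            if granules[i] & members:
                upper[c].add(i)
    all_upper = set().union(*upper.values())
    all_lower = set().union(*lower.values())
    return lower, upper, all_upper - all_lower


def brute_nearest_neighbor(table: HybridTable, query, params: DistanceParams) -> str:
    """1-NN with the package's stated tie-break cascade, computed by hand.

    At r = 0 the neighborhood is exactly the argmin set, every member is at
    the same (minimal) distance, so the plurality class wins and remaining
    ties fall through to the lexicographically smallest label.
    """
    labels = table.labels
    recs = table.records()
    d = np.array([hybrid_distance(rec, query, params) for rec in recs])
    at_min = np.flatnonzero(d == d.min())
    votes: dict[str, int] = {}
    for i in at_min:
        votes[labels[i]] = votes.get(labels[i], 0) + 1
    top = max(votes.values())
    tied = sorted(c for c, v in votes.items() if v == top)
    return tied[0]
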