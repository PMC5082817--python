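"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the code paths (and, where feasible, the
libraries) they verify: the hypergeometric tail is summed directly from
log-factorials, BH is the textbook step-up formula, and TOM is a naive
triple loop.
"""

from math import comb

import numpy as np


def hypergeom_tail(a: int, N: int, K: int, n: int) -> float:
    """P(X >= a) for X ~ Hypergeometric(N, K, n).

    Exact integer enumeration: the tail is a ratio of big-integer
    binomial sums; CPython's int/int division rounds correctly, so the
    oracle is accurate to 1/2 ulp at any table size.
    """
    lo = max(a, max(0, K + n - N))
    hi = min(K, n)
    if lo > hi:
        return 0.0
    numerator = sum(comb(K, k) * comb(N - K, n - k) for k in range(lo, hi + 1))
    return numerator / comb(N, n)


def bh_stepup(p) -> np.ndarray:
    """adj_i = min_{k >= rank(i)} m * p_(k) / k, capped at 1."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * p[i] / rank)
        adj[i] = running
    return adj


def tom_triple_loop(adjacency: np.ndarray) -> np.ndarray:
    """Naive unsigned topological overlap."""
    a = np.array(adjacency, dtype=float)
    n = a.shape[0]
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    t = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            s = 0.0
            for u in range(n):
                s += a[i, u] * a[u, j]
            t[i, j] = (s + a[i, j]) / (min(k[i], k[j]) + 1.0 - a[i, j])
    return t
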