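"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the code paths (scipy.stats.hypergeom,
statsmodels.multipletests, networkx) used by the package itself.
"""

from __future__ import annotations

from decimal import Decimal, getcontext
from math import exp, fsum, lgamma

import numpy as np


def bh_stepup(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, written from the definition."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adjusted = np.empty(m)
    running_min = 1.0
    for i in range(m - 1, -1, -1):
        rank = i + 1
        running_min = min(running_min, p[order[i]] * m / rank)
        adjusted[order[i]] = running_min
    return adjusted


def _log_choose(n: int, k: int) -> float:
    return lgamma(n + 1) - lgamma(k + 1) - lgamma(n - k + 1)


def hypergeom_pmf(N: int, K: int, n: int, x: int) -> float:
    """P(X = x) for X ~ Hypergeometric(N, K, n), via exact log-factorials."""
    if x < 0 or x > K or n - x < 0 or n - x > N - K:
        return 0.0
    return exp(_log_choose(K, x) + _log_choose(N - K, n - x) - _log_choose(N, n))


def hypergeom_tail(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) by brute-force summation of point masses."""
    if k <= 0:
        return 1.0
    return min(1.0, fsum(hypergeom_pmf(N, K, n, x) for x in range(k, min(n, K) + 1)))


def gwrs_highprec(r: int, m: int, prec: int = 50) -> float:
    """-2*ln(r/m) evaluated in 50-digit decimal arithmetic."""
    getcontext().prec = prec
    return float(-2 * (Decimal(r) / Decimal(m)).ln())


def degrees_bruteforce(edges, node_subset) -> dict[str, int]:
    """Distinct-neighbour degree count over edges restricted to a node set."""
    neighbours: dict[str, set[str]] = {}
    for a, b, *_ in edges:
        if a in node_subset and b in node_subset and a != b:
            neighbours.setdefault(a, set()).add(b)
            neighbours.setdefault(b, set()).add(a)
    return {g: len(ns) for g, ns in neighbours.items()}
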