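"""Independent brute-force oracles used by the test suite.

Everything here is written from first principles (exhaustive enumeration,
closed forms) and deliberately avoids the code paths — and the libraries —
that the package uses for the same quantities.
"""

from __future__ import annotations

import math

import numpy as np

REL_TIE_TOL = 1e-12  # relative tolerance for detecting tied shortest-path lengths


def enumerate_simple_paths(dist: np.ndarray, src: int, dst: int):
    """All simple paths src -> dst over finite-distance edges, with lengths."""
    n = dist.shape[0]
    paths = []

    def extend(path, length):
        last = path[-1]
        if last == dst:
            paths.append((list(path), length))
            return
        for nxt in range(n):
            if nxt in path or not np.isfinite(dist[last, nxt]) or nxt == last:
                continue
            path.append(nxt)
            extend(path, length + dist[last, nxt])
            path.pop()

    extend([src], 0.0)
    return paths


def brute_force_betweenness(dist: np.ndarray) -> np.ndarray:
    """Eq.-style weighted BC by exhaustive simple-path enumeration (n <= 8).

    For every unordered endpoint pair the minimal-length simple paths are
    found (ties within REL_TIE_TOL); each interior node's share of those
    paths is accumulated and the total is normalized by the (n-1)(n-2)
    ordered endpoint pairs. Infinite-distance pairs contribute nothing.
    """
    n = dist.shape[0]
    bc = np.zeros(n)
    for h in range(n):
        for j in range(h + 1, n):
            paths = enumerate_simple_paths(dist, h, j)
            if not paths:
                continue
            best = min(length for _, length in paths)
            shortest = [p for p, length in paths
                        if length <= best * (1 + REL_TIE_TOL)]
            sp = len(shortest)
            for i in range(n):
                if i in (h, j):
                    continue
                through = sum(1 for p in shortest if i in p[1:-1])
                # unordered pair counted once; ordered-pair sum doubles both
                # numerator and denominator, so add twice the share
                bc[i] += 2.0 * through / sp
    return bc / ((n - 1) * (n - 2))


def floyd_warshall_aspl(dist: np.ndarray) -> float:
    """ASPL via a hand-rolled Floyd-Warshall; mean over finite ordered pairs."""
    d = dist.copy()
    n = d.shape[0]
    np.fill_diagonal(d, 0.0)
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    total, count = 0.0, 0
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(d[i, j]):
                total += d[i, j]
                count += 1
    if count == 0:
        raise ValueError("no finite pairs")
    return total / count


def literal_weak_monotonicity(values, max_violations: int = 1) -> str:
    """A literal, loop-based restatement of the weak-monotonicity rule.

    Returns "increasing", "decreasing" or "none". Written independently of
    the package classifier: walks adjacent pairs, counts strict reversals
    against each candidate trend, then applies the endpoint conditions.
    """
    v = list(values)
    up_breaks = 0
    down_breaks = 0
    for a, b in zip(v[:-1], v[1:]):
        if b < a:
            up_breaks += 1
        if b > a:
            down_breaks += 1
    if v[-1] > v[0] and up_breaks <= max_violations:
        return "increasing"
    if v[-1] < v[0] and down_breaks <= max_violations:
        return "decreasing"
    return "none"


def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p by full enumeration over fixed margins.

    Table [[a, b], [c, d]]; sums the hypergeometric probabilities of every
    table (with the same margins) whose point probability does not exceed
    the observed table's.
    """
    r1, r2 = a + b, c + d
    c1 = a + c
    ntot = r1 + r2

    def pmf(x: int) -> float:
        return (
            math.comb(r1, x) * math.comb(r2, c1 - x) / math.comb(ntot, c1)
        )

    lo, hi = max(0, c1 - r2), min(r1, c1)
    p_obs = pmf(a)
    return sum(pmf(x) for x in range(lo, hi + 1) if pmf(x) <= p_obs * (1 + 1e-9))


def one_factor_correlation(c1: float, c2: float, noise_sd: float) -> float:
    """Closed-form Pearson correlation of a one-factor model with unit-variance
    factor: r = c1*c2 / sqrt((c1^2 + sd^2)(c2^2 + sd^2))."""
    return c1 * c2 / math.sqrt((c1**2 + noise_sd**2) * (c2**2 + noise_sd**2))
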