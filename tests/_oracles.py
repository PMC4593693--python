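"""Independent brute-force oracles used by the test suite.

Every oracle here recomputes a quantity by a route independent of the
implementation it checks: exhaustive path enumeration for betweenness,
bisection on tail probabilities for quantiles, explicit ranking for the
rank correlation, and grid search for the marginal-likelihood fit.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.special import betainc, betaln
from scipy.stats import binom


def brute_force_betweenness(weights: np.ndarray) -> np.ndarray:
    """Betweenness by enumerating every simple path between every pair.

    Edge lengths are 1/weight; shortest paths are found by exhaustive
    enumeration, ties split fractionally, pairs counted unordered. Only
    feasible for tiny graphs (<= ~7 nodes).
    """
    n = weights.shape[0]
    bc = np.zeros(n)
    nodes = list(range(n))
    for s, t in itertools.combinations(nodes, 2):
        others = [v for v in nodes if v not in (s, t)]
        lengths: list[tuple[float, tuple[int, ...]]] = []
        for r in range(len(others) + 1):
            for mid in itertools.permutations(others, r):
                path = (s,) + mid + (t,)
                total = 0.0
                ok = True
                for u, v in zip(path[:-1], path[1:]):
                    w = weights[u, v]
                    if w <= 0:
                        ok = False
                        break
                    total += 1.0 / w
                if ok:
                    lengths.append((total, path))
        if not lengths:
            continue
        best = min(l for l, _ in lengths)
        shortest = [p for l, p in lengths if l == best]
        for p in shortest:
            for v in p[1:-1]:
                bc[v] += 1.0 / len(shortest)
    return bc


def spearman_oracle(x, y) -> float:
    """Rank correlation by explicit average-rank assignment plus Pearson."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)

    def avg_ranks(v):
        return np.array(
            [np.sum(v < vi) + (np.sum(v == vi) + 1) / 2.0 for vi in v]
        )

    rx, ry = avg_ranks(x), avg_ranks(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(np.sum(rx * ry) / np.sqrt(np.sum(rx**2) * np.sum(ry**2)))


def beta_quantile_bisect(p: float, a: float, b: float, tol: float = 1e-12) -> float:
    """Beta quantile by bisection on the regularized incomplete beta."""
    lo, hi = 0.0, 1.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if betainc(a, b, mid) < p:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def clopper_pearson_bisect(d: int, s: int, level: float = 0.95) -> tuple[float, float]:
    """Exact binomial interval by bisection on binomial tail probabilities."""
    tail = (1.0 - level) / 2.0

    def bisect(f, increasing, tol=1e-12):
        lo, hi = 0.0, 1.0
        while hi - lo > tol:
            mid = 0.5 * (lo + hi)
            val = f(mid)
            if (val < tail) == increasing:
                lo = mid
            else:
                hi = mid
        return 0.5 * (lo + hi)

    # lower solves P(X >= d | p) = tail (increasing in p)
    lower = 0.0 if d == 0 else bisect(lambda p: binom.sf(d - 1, s, p), True)
    # upper solves P(X <= d | p) = tail (decreasing in p)
    upper = 1.0 if d == s else bisect(lambda p: binom.cdf(d, s, p), False)
    return lower, upper


def log_marginal_grid_max(
    d, s, a_grid, b_grid
) -> tuple[float, float, float]:
    """Grid-search maximum of the beta-binomial log marginal likelihood."""
    d = np.asarray(d, dtype=float)
    s = np.asarray(s, dtype=float)
    best = (-np.inf, np.nan, np.nan)
    for a in a_grid:
        for b in b_grid:
            val = float(np.sum(betaln(a + d, b + s - d) - betaln(a, b)))
            if val > best[0]:
                best = (val, a, b)
    return best
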