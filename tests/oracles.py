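"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the code paths they verify: cluster finding by
O(n^2) pairwise transitive closure, Fisher p-values by the factorial
formula over enumerated tables, BH by the textbook step-up formula, and
NNLS by dense grid search over the contribution simplex.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np


def brute_force_clusters(positions: list[int], max_distance: int) -> list[frozenset[int]]:
    """Transitive closure of the pairwise within-distance relation.

    Returns the member-position sets of all components of size >= 2.
    """
    pos = list(positions)
    parent = list(range(len(pos)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in combinations(range(len(pos)), 2):
        if abs(pos[i] - pos[j]) <= max_distance:
            parent[find(i)] = find(j)
    comps: dict[int, set[int]] = {}
    for i in range(len(pos)):
        comps.setdefault(find(i), set()).add(pos[i])
    return [frozenset(c) for c in comps.values() if len(c) >= 2]


def fisher_oracle(a: int, b: int, c: int, d: int, sided: str = "two") -> float:
    """Fisher's exact p for [[a,b],[c,d]] by hypergeometric enumeration.

    Point probabilities come straight from the factorial formula
    C(r1,x) C(r2, c1-x) / C(n, c1); the two-sided p sums probabilities of
    tables at most as probable as the observed one (with a small relative
    tolerance for float ties, matching the conventional definition).
    """
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    lo, hi = max(0, c1 - r2), min(r1, c1)
    denom = math.comb(n, c1)
    pmf = {x: math.comb(r1, x) * math.comb(r2, c1 - x) / denom for x in range(lo, hi + 1)}
    p_obs = pmf[a]
    if sided == "greater":
        return min(1.0, sum(p for x, p in pmf.items() if x >= a))
    return min(1.0, sum(p for p in pmf.values() if p <= p_obs * (1 + 1e-7)))


def bh_oracle(p_values: list[float]) -> np.ndarray:
    """Step-up Benjamini-Hochberg: q_(i) = min_{j>=i} p_(j) * m / j."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def simplex_grid(k: int, step: float = 0.01) -> np.ndarray:
    """All contribution vectors on the k-simplex with the given step."""
    n = round(1 / step)
    if k == 1:
        return np.array([[1.0]])
    if k == 2:
        i = np.arange(n + 1)
        return np.column_stack([i, n - i]) / n
    if k == 3:
        pts = [(i, j, n - i - j) for i in range(n + 1) for j in range(n + 1 - i)]
        return np.asarray(pts, dtype=float) / n
    raise ValueError("grid oracle supports k <= 3")


def grid_search_residual(catalog: np.ndarray, matrix: np.ndarray, step: float = 0.01) -> float:
    """Best residual norm over the contribution simplex with optimal scale.

    For each grid contribution c, the non-negative scale s minimising
    ||y - s M c|| has the closed form max(0, y.(Mc)/||Mc||^2).
    """
    y = np.asarray(catalog, dtype=float)
    grid = simplex_grid(matrix.shape[1], step)
    mc = grid @ matrix.T  # (n_grid, 96)
    norms2 = np.einsum("ij,ij->i", mc, mc)
    dots = mc @ y
    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.where(norms2 > 0, np.maximum(dots / norms2, 0.0), 0.0)
    res2 = y @ y - 2 * s * dots + s**2 * norms2
    return float(np.sqrt(max(res2.min(), 0.0)))
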