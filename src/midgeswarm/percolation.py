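"""Percolation analysis of swarm configurations.

Link two individuals when their distance is strictly below a scale λ and
track the fraction n(λ) of the group inside the largest connected cluster.
n(λ) is non-decreasing and jumps only at pairwise distances; the
percolation threshold λc is the smallest λ at which a giant cluster
(fraction ≥ θ of the group) exists.  Across swarms of different density λc
scales with the nearest-neighbour distance r1, so the dimensionless slope
s = λc/r1 converts a transition located in units of r1 into a metric
interaction range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree


class ThresholdError(RuntimeError):
    """No percolation threshold inside the examined range."""


@dataclass
class PercolationCurve:
    lambdas: np.ndarray          # sorted linking scales, metres
    fractions: np.ndarray        # n(lambda), in [1/N, 1]
    threshold: float             # lambda_c, metres
    threshold_fraction: float    # theta used


class _UnionFind:
    """Weighted quick-union with path compression."""

    def __init__(self, n: int) -> None:
        self.parent = np.arange(n)
        self.size = np.ones(n, dtype=int)

    def find(self, i: int) -> int:
        root = i
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[i] != root:
            self.parent[i], i = root, self.parent[i]
        return root

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri == rj:
            return
        if self.size[ri] < self.size[rj]:
            ri, rj = rj, ri
        self.parent[rj] = ri
        self.size[ri] += self.size[rj]

    def largest(self) -> int:
        roots = np.array([self.find(i) for i in range(len(self.parent))])
        return int(np.bincount(roots).max())


def _linked_pairs(positions: np.ndarray, lam: float):
    """Pairs with r_ij strictly below lam."""
    tree = cKDTree(positions)
    pairs = tree.query_pairs(lam, output_type="ndarray")
    if len(pairs) == 0:
        return pairs
    d = np.linalg.norm(positions[pairs[:, 0]] - positions[pairs[:, 1]], axis=1)
    return pairs[d < lam]


def cluster_fraction(positions: np.ndarray, lam: float) -> float:
    """Largest-cluster fraction of the graph linking pairs with r_ij < λ."""
    positions = np.asarray(positions, float)
    n = positions.shape[0]
    if n < 2:
        raise ValueError("cluster fraction needs N >= 2")
    if lam <= 0:
        raise ValueError("linking scale must be positive")
    uf = _UnionFind(n)
    for i, j in _linked_pairs(positions, lam):
        uf.union(int(i), int(j))
    return uf.largest() / n


def percolation_threshold(
    positions: np.ndarray,
    theta: float = 0.6,
    lambda_grid: np.ndarray | None = None,
    rel_tol: float = 1e-3,
) -> PercolationCurve:
    """λc = smallest λ with n(λ) ≥ θ, refined by bisection.

    The default grid spans the minimum and maximum pairwise distances in 50
    steps; the straddling grid interval is then bisected to a relative width
    of ``rel_tol``.
    """
    positions = np.asarray(positions, float)
    n = positions.shape[0]
    if not 1 / n <= theta <= 1:
        raise ValueError("theta must lie in [1/N, 1]")
    from scipy.spatial.distance import pdist

    dists = pdist(positions)
    if lambda_grid is None:
        lambda_grid = np.linspace(dists.min(), dists.max(), 50)
    lambda_grid = np.sort(np.asarray(lambda_grid, float))
    fractions = np.array([cluster_fraction(positions, l) for l in lambda_grid])
    above = fractions >= theta
    if not above.any():
        hi = float(dists.max()) * (1 + rel_tol)
        if cluster_fraction(positions, hi) < theta:
            raise ThresholdError("no giant cluster within the examined range")
        lo = float(lambda_grid[-1])
    else:
        k = int(np.argmax(above))
        hi = float(lambda_grid[k])
        lo = float(lambda_grid[k - 1]) if k > 0 else 0.0
    while (hi - lo) > rel_tol * hi:
        mid = 0.5 * (lo + hi)
        if cluster_fraction(positions, mid) >= theta:
            hi = mid
        else:
            lo = mid
    return PercolationCurve(lambda_grid, fractions, float(hi), float(theta))


def threshold_scaling(
    events: list[tuple[float, float]],
    n_boot: int = 1000,
    seed: int | np.random.Generator = 0,
) -> tuple[float, tuple[float, float]]:
    """Through-origin least-squares slope of λc against r1, with bootstrap CI.

    ``events`` are per-swarm pairs ``(r1, λc)``; the fitted proportionality
    ``λc = s·r1`` is the dimensionless percolation threshold.  Returns
    ``(s, (lo, hi))`` with a 95% percentile bootstrap interval over events.
    """
    if len(events) < 3:
        raise ValueError("threshold scaling needs at least 3 events")
    r1 = np.array([e[0] for e in events], float)
    lam = np.array([e[1] for e in events], float)

    def slope(r: np.ndarray, l: np.ndarray) -> float:
        return float(np.dot(r, l) / np.dot(r, r))

    s = slope(r1, lam)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    boots = []
    for _ in range(n_boot):
        idx = rng.integers(0, len(r1), len(r1))
        boots.append(slope(r1[idx], lam[idx]))
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return s, (float(lo), float(hi))
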