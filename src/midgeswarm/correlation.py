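"""Connected correlation, correlation length and susceptibility.

Given dimensionless velocity fluctuations φ_i (normalized so that
(1/N) Σ φ_i·φ_i = 1) at positions x_i, the connected correlation function is
the binned pair average

    C(r) = Σ_{i≠j} φ_i·φ_j δ(r − r_ij) / Σ_{i≠j} δ(r − r_ij)

with contiguous bins of width δr from zero.  Its first zero crossing r0
measures the spatial span of the correlated fluctuations.  The cumulative
correlation

    Q(r) = (1/N) Σ_{i≠j} φ_i·φ_j θ(r − r_ij)

integrates both span and intensity; its maximum χ = max_r Q(r) plays the
role of a susceptibility.  Because Σ_i φ_i = 0 and (1/N) Σ |φ_i|² = 1,
Q(r) → −1 exactly once r exceeds the largest pair distance — a built-in
normalization check used throughout the tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist

from .io import PairwiseSample, SwarmTrajectory
from .modes import DegenerateFrameError, decompose

DEFAULT_BINS_PER_SPAN = 50


@dataclass
class CorrelationCurve:
    """Binned connected correlation with pair counts.

    ``values`` is NaN where ``pair_counts`` is zero (an empty bin carries no
    estimate, it is not zero correlation).  ``r0`` is filled in by
    :func:`correlation_length` and may be None when C never changes sign.
    """

    bin_centers: np.ndarray
    values: np.ndarray
    pair_counts: np.ndarray
    bin_width: float
    r0: float | None = None


@dataclass
class SusceptibilityResult:
    """Cumulative correlation Q on a grid and its maximum χ."""

    grid: np.ndarray
    q_curve: np.ndarray
    chi: float
    argmax_r: float
    per_frame: list = field(default_factory=list)
    mean: float | None = None
    sd: float | None = None
    n_skipped: int = 0


def _binned(r: np.ndarray, dots: np.ndarray, bin_width: float | None) -> CorrelationCurve:
    if bin_width is None:
        span = float(r.max()) if r.size else 1.0
        bin_width = span / DEFAULT_BINS_PER_SPAN if span > 0 else 1.0
    if r.size == 0:
        return CorrelationCurve(
            np.empty(0), np.empty(0), np.empty(0, dtype=int), bin_width
        )
    n_bins = int(np.floor(r.max() / bin_width)) + 1
    idx = np.minimum((r / bin_width).astype(int), n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    sums = np.bincount(idx, weights=dots, minlength=n_bins)
    values = np.full(n_bins, np.nan)
    populated = counts > 0
    values[populated] = sums[populated] / counts[populated]
    centers = (np.arange(n_bins) + 0.5) * bin_width
    return CorrelationCurve(centers, values, counts, float(bin_width))


def connected_correlation(
    phi: np.ndarray, positions: np.ndarray, bin_width: float | None = None
) -> CorrelationCurve:
    """Binned C(r) over all i≠j pairs; self-pairs are excluded.

    ``bin_width`` defaults to (max pair distance)/50.
    """
    phi = np.asarray(phi, float)
    positions = np.asarray(positions, float)
    if positions.shape[0] < 2:
        raise DegenerateFrameError("correlation needs N >= 2")
    r = pdist(positions)
    dots = _pair_dots(phi)
    return _binned(r, dots, bin_width)


def _pair_dots(phi: np.ndarray) -> np.ndarray:
    """Upper-triangle φ_i·φ_j without forming the N×N Gram matrix twice."""
    gram = phi @ phi.T
    iu = np.triu_indices(len(phi), k=1)
    return gram[iu]


def correlation_length(curve: CorrelationCurve) -> float | None:
    """First zero of C(r), by linear interpolation between populated bins.

    Returns None when C never changes sign.  A curve that is already
    negative in its first populated bin returns that bin's lower edge.
    """
    ok = curve.pair_counts > 0
    centers = curve.bin_centers[ok]
    vals = curve.values[ok]
    if len(vals) < 2:
        return None
    if vals[0] < 0:
        return float(max(centers[0] - curve.bin_width / 2, 0.0))
    for i in range(len(vals) - 1):
        a, b = vals[i], vals[i + 1]
        if a >= 0 > b or (a > 0 and b == 0):
            if b == 0:
                return float(centers[i + 1])
            frac = a / (a - b)
            return float(centers[i] + frac * (centers[i + 1] - centers[i]))
    return None


def susceptibility(
    phi: np.ndarray,
    positions: np.ndarray,
    grid: np.ndarray | None = None,
    bin_width: float | None = None,
) -> SusceptibilityResult:
    """Q(r) on a grid and its maximum χ.

    The default grid is the bin-edge grid of the matching C(r) (including
    r = 0 and one edge beyond the largest pair distance), so the location of
    the maximum can be compared with the first zero of C bin for bin.
    """
    phi = np.asarray(phi, float)
    positions = np.asarray(positions, float)
    n = positions.shape[0]
    if n < 2:
        raise DegenerateFrameError("susceptibility needs N >= 2")
    r = pdist(positions)
    dots = _pair_dots(phi)
    if grid is None:
        span = float(r.max())
        if bin_width is None:
            bin_width = span / DEFAULT_BINS_PER_SPAN if span > 0 else 1.0
        n_edges = int(np.floor(span / bin_width)) + 2
        grid = np.arange(n_edges + 1) * bin_width
    grid = np.asarray(grid, float)
    order = np.argsort(r)
    r_sorted = r[order]
    cum = np.concatenate([[0.0], np.cumsum(dots[order])])
    # ordered pairs: twice the cumulative unordered sum, divided by N
    q = 2.0 * cum[np.searchsorted(r_sorted, grid, side="right")] / n
    k = int(np.argmax(q))
    return SusceptibilityResult(grid, q, float(q[k]), float(grid[k]))


def frame_pair_statistics(
    traj: SwarmTrajectory, bin_width: float | None = None
) -> list[dict]:
    """Per-frame-pair decomposition, correlation and susceptibility.

    Skips pairs the mode decomposition cannot handle (too small, collinear)
    and records them; used by the event pipeline and the time-series
    susceptibility.
    """
    stats = []
    for fa, fb in traj.frame_pairs():
        try:
            dec = decompose(fa, fb, traj.fps)
            curve = connected_correlation(dec.phi, fa.positions, bin_width)
            curve.r0 = correlation_length(curve)
            sus = susceptibility(dec.phi, fa.positions, bin_width=bin_width)
        except DegenerateFrameError:
            stats.append({"time_index": fa.time_index, "skipped": True})
            continue
        stats.append(
            {
                "time_index": fa.time_index,
                "skipped": False,
                "decomposition": dec,
                "curve": curve,
                "chi": sus.chi,
                "argmax_r": sus.argmax_r,
                "r0": curve.r0,
            }
        )
    return stats


def susceptibility_timeseries(
    traj: SwarmTrajectory, bin_width: float | None = None
) -> SusceptibilityResult:
    """Per-frame χ with acquisition mean and standard deviation."""
    stats = frame_pair_statistics(traj, bin_width)
    chis = [s["chi"] for s in stats if not s["skipped"]]
    n_skipped = sum(s["skipped"] for s in stats)
    if len(chis) < 2:
        raise DegenerateFrameError("need at least two usable frame pairs")
    chis = np.asarray(chis)
    return SusceptibilityResult(
        grid=np.empty(0),
        q_curve=np.empty(0),
        chi=float(chis.mean()),
        argmax_r=float("nan"),
        per_frame=list(chis),
        mean=float(chis.mean()),
        sd=float(chis.std(ddof=1)),
        n_skipped=n_skipped,
    )


def correlation_from_pairwise(
    samples: list[PairwiseSample], bin_width: float | None = None
) -> CorrelationCurve:
    """C(r) from precomputed (distance, φ_i·φ_j) rows.

    Same estimator as :func:`connected_correlation`, for the two-column
    supplementary pairwise files.
    """
    if not samples:
        return CorrelationCurve(
            np.empty(0), np.empty(0), np.empty(0, dtype=int), bin_width or 1.0
        )
    r = np.array([s.distance for s in samples])
    dots = np.array([s.dot for s in samples])
    curve = _binned(r, dots, bin_width)
    curve.r0 = correlation_length(curve)
    return curve
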