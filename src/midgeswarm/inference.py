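"""Statistical layer: permutation tests, critical-scaling fit, range estimate.

Three pieces of inference sit on top of the per-swarm measurements:

* a **permutation test** on the Spearman rank correlation — the P-value is
  the fraction of random re-pairings whose |ρ| is at least as extreme as
  the observed one (with the +1 small-sample correction so P > 0);
* the **critical scaling fit** χ = a·(x − x_c)^(−γ) on the disordered
  branch x > x_c, fitted on log χ with a profiled 1D search over x_c and
  bootstrap confidence intervals (the fit is notoriously unstable, so
  intervals — not point values — are the deliverable);
* the **interaction-range estimate** combining the fitted transition point
  x_c (in body lengths) with the percolation slope s = λc/r1 into
  rc/BL = x_c·s, with delta-method error propagation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats


class InvalidBranchError(RuntimeError):
    """Susceptibility not decreasing with x: not a disordered-branch data set."""


class NonIdentifiableError(RuntimeError):
    """The scaling fit cannot pin down a transition point."""


@dataclass
class PermutationTestResult:
    rho: float
    p_value: float
    n_permutations: int
    seed: int


@dataclass
class ScalingFit:
    amplitude: float
    x_c: float
    gamma: float
    ci: dict = field(default_factory=dict)     # parameter -> (lo, hi), 95%
    rss: float = float("nan")                  # residual sum of squares on log chi
    n_points: int = 0
    n_boot_failed: int = 0


def permutation_pvalue(
    x: np.ndarray,
    y: np.ndarray,
    m: int = 10_000,
    seed: int = 0,
) -> PermutationTestResult:
    """Spearman ρ with a two-sided permutation P-value.

    ``P = (1 + #{|ρ_perm| >= |ρ_obs|}) / (m + 1)`` over ``m`` random
    re-pairings of y; ties get average ranks.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 5:
        raise ValueError("need at least 5 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant variable: Spearman rho undefined")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    denom = np.sqrt(np.dot(rxc, rxc) * np.dot(ryc, ryc))
    rho = float(np.dot(rxc, ryc) / denom)
    rng = np.random.default_rng(seed)
    perms = rng.permuted(np.tile(ryc, (m, 1)), axis=1)
    rho_perm = perms @ rxc / denom
    n_extreme = int(np.sum(np.abs(rho_perm) >= abs(rho) - 1e-12))
    return PermutationTestResult(
        rho=rho, p_value=(1 + n_extreme) / (m + 1), n_permutations=m, seed=seed
    )


def compare_scaling_variables(
    r1: np.ndarray,
    body_length: np.ndarray,
    chi: np.ndarray,
    m: int = 10_000,
    seed: int = 0,
) -> tuple[PermutationTestResult, PermutationTestResult]:
    """P-values of χ against the rescaled and the bare nearest-neighbour distance.

    Returns ``(test for x = r1/BL, test for x = r1)``.  A markedly smaller
    P-value for r1/BL is the signature of a metric interaction whose range
    is set by the insect's body length.
    """
    r1 = np.asarray(r1, float)
    bl = np.asarray(body_length, float)
    chi = np.asarray(chi, float)
    return (
        permutation_pvalue(r1 / bl, chi, m=m, seed=seed),
        permutation_pvalue(r1, chi, m=m, seed=seed),
    )


def _profiled_fit(
    x: np.ndarray, log_chi: np.ndarray, x_c: float, w: np.ndarray | None = None
):
    """Closed-form weighted (log a, gamma) for fixed x_c.

    Returns (weighted rss, log_a, gamma); ``w`` are inverse-variance weights
    on log chi (uniform when None).
    """
    t = np.log(x - x_c)
    if w is None:
        w = np.ones_like(t)
    wsum = w.sum()
    tbar = np.dot(w, t) / wsum
    lbar = np.dot(w, log_chi) / wsum
    tc = t - tbar
    lc = log_chi - lbar
    denom = np.dot(w, tc * tc)
    if denom == 0:
        return np.inf, 0.0, 0.0
    slope = np.dot(w, tc * lc) / denom
    gamma = -slope
    log_a = lbar + gamma * tbar
    resid = lc - slope * tc
    return float(np.dot(w, resid * resid)), float(log_a), float(gamma)


def _fit_once(
    x: np.ndarray,
    chi: np.ndarray,
    x_c_min: float | None = None,
    w: np.ndarray | None = None,
) -> tuple[float, float, float, float]:
    """Multi-start profiled fit. Returns (a, x_c, gamma, rss).

    ``x_c_min`` optionally bounds the transition point from below (e.g. 0
    when x is a positive ratio and a divergence at non-positive x is
    unphysical).
    """
    log_chi = np.log(chi)
    x_min = float(x.min())
    span = float(np.ptp(x)) or abs(x_min) or 1.0
    lo = x_min - span * 100.0 if x_c_min is None else float(x_c_min)
    hi = x_min - span * 1e-9
    if lo >= hi:
        raise NonIdentifiableError("no admissible transition point below the data")
    # candidate transition points strictly below the data range
    offsets = span * np.geomspace(1e-6, 50.0, 40)
    candidates = x_min - offsets
    candidates = candidates[candidates > lo]
    if len(candidates) == 0:
        candidates = np.array([0.5 * (lo + hi)])
    best = (np.inf, None)
    for xc in candidates:
        rss, _, _ = _profiled_fit(x, log_chi, xc, w)
        if rss < best[0]:
            best = (rss, xc)
    xc0 = best[1]

    def objective(xc: float) -> float:
        return _profiled_fit(x, log_chi, xc, w)[0]

    res = optimize.minimize_scalar(
        objective,
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-12 * span},
    )
    xc = float(res.x) if res.fun <= objective(xc0) else float(xc0)
    rss, log_a, gamma = _profiled_fit(x, log_chi, xc, w)
    if x_c_min is None and (x_min - xc) > span * 99.0:
        raise NonIdentifiableError("transition point runs away below the data range")
    if not np.isfinite(log_a) or abs(log_a) > 700:
        raise NonIdentifiableError("degenerate amplitude in scaling fit")
    return float(np.exp(log_a)), xc, gamma, rss


def fit_critical_scaling(
    x: np.ndarray,
    chi: np.ndarray,
    n_boot: int = 300,
    seed: int = 0,
    x_c_min: float | None = None,
    sigma: np.ndarray | None = None,
) -> ScalingFit:
    """Fit χ = a·(x − x_c)^(−γ) on the disordered branch.

    The fit is least squares on log χ with the amplitude and exponent
    profiled out, leaving a 1D search over x_c (grid multi-start plus
    bounded refinement).  Confidence intervals are 95% percentile bootstrap
    over points.  ``x_c_min`` restricts the transition point (pass 0 when x
    is a positive density ratio, where a divergence at non-positive x is
    unphysical).  ``sigma``, when given, holds per-point standard errors of
    χ; the fit then uses inverse-variance weights on log χ (delta method:
    sd(log χ) = sigma/χ), so precisely measured points near the transition
    anchor the divergence.

    Raises
    ------
    InvalidBranchError
        If χ does not decrease with x (Spearman ρ ≥ 0) or the fitted
        exponent is not positive.
    NonIdentifiableError
        If the optimal x_c runs away far below the data range (no
        transition in sight, e.g. null-model input).
    """
    x = np.asarray(x, float)
    chi = np.asarray(chi, float)
    if len(x) < 6:
        raise ValueError("need at least 6 points on the disordered branch")
    if np.any(chi <= 0):
        raise ValueError("susceptibility values must be positive")
    rho = stats.spearmanr(x, chi).statistic
    if rho >= 0:
        raise InvalidBranchError(
            f"susceptibility increases with x (Spearman rho = {rho:.2f})"
        )
    w = None
    if sigma is not None:
        sigma = np.asarray(sigma, float)
        if np.any(sigma <= 0):
            raise ValueError("sigma values must be positive")
        w = (chi / sigma) ** 2
    a, xc, gamma, rss = _fit_once(x, chi, x_c_min, w)
    if gamma <= 0:
        raise InvalidBranchError(f"fitted exponent not positive (gamma = {gamma:.3f})")
    rng = np.random.default_rng(seed)
    boots = {"amplitude": [], "x_c": [], "gamma": []}
    n_failed = 0
    for _ in range(n_boot):
        idx = rng.integers(0, len(x), len(x))
        if len(np.unique(x[idx])) < 3:
            n_failed += 1
            continue
        try:
            wb = None if w is None else w[idx]
            ab, xcb, gb, _ = _fit_once(x[idx], chi[idx], x_c_min, wb)
        except (NonIdentifiableError, FloatingPointError):
            n_failed += 1
            continue
        boots["amplitude"].append(ab)
        boots["x_c"].append(xcb)
        boots["gamma"].append(gb)
    ci = {
        k: tuple(np.percentile(v, [2.5, 97.5])) if v else (float("nan"), float("nan"))
        for k, v in boots.items()
    }
    return ScalingFit(
        amplitude=a, x_c=xc, gamma=gamma, ci=ci, rss=rss,
        n_points=len(x), n_boot_failed=n_failed,
    )


def estimate_interaction_range(
    xc_bl: float,
    s: float,
    ci_xc: tuple[float, float] | None = None,
    ci_s: tuple[float, float] | None = None,
) -> tuple[float, tuple[float, float]]:
    """Metric interaction range in body lengths: rc/BL = x_c · s.

    ``xc_bl`` is the fitted transition point of χ(r1/BL); ``s`` the
    percolation slope λc/r1.  At the transition r1 = x_c·BL while the
    alignment graph percolates when rc = s·r1, hence rc = x_c·s·BL.  The
    confidence interval is the interval image of the product: on the
    positive domain rc is monotone in both inputs, so the endpoint
    products bound it exactly (and stay faithful to the skew of a
    bootstrap interval, which a symmetric delta-method band would not).
    A missing input interval is treated as exact.
    """
    if xc_bl <= 0 or s <= 0:
        raise ValueError("transition point and percolation slope must be positive")
    rc_bl = xc_bl * s
    lo_x, hi_x = ci_xc if ci_xc is not None else (xc_bl, xc_bl)
    lo_s, hi_s = ci_s if ci_s is not None else (s, s)
    if lo_x < 0 or lo_s < 0:
        lo_x, lo_s = max(lo_x, 0.0), max(lo_s, 0.0)
    return float(rc_bl), (float(lo_x * lo_s), float(hi_x * hi_s))
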