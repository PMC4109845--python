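"""Per-event analysis and cross-event inference.

``analyze_event`` runs the full chain on one acquisition — velocities,
collective-mode subtraction, order parameters, connected correlation and
its first zero, susceptibility, per-frame percolation threshold — and
aggregates to an :class:`EventSummary` (one row of the cross-swarm table).
``cross_event_report`` then asks the cross-swarm questions: is χ better
predicted by r1/BL than by r1 (metric interaction), where is the
transition point, what is the percolation slope, and hence what metric
interaction range do the two combine to?
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field

import numpy as np

from .correlation import frame_pair_statistics
from .inference import (
    InvalidBranchError,
    NonIdentifiableError,
    compare_scaling_variables,
    estimate_interaction_range,
    fit_critical_scaling,
)
from .io import SwarmTrajectory, nearest_neighbour_distance
from .modes import DegenerateFrameError, order_parameters
from .percolation import percolation_threshold, threshold_scaling

logger = logging.getLogger(__name__)


class EventRejected(RuntimeError):
    """Acquisition unusable for the per-event analysis."""


@dataclass
class AnalysisConfig:
    """Knobs of the per-event chain (defaults match the package defaults)."""

    bin_width: float | None = None       # None -> max pair distance / 50
    percolation_theta: float = 0.6
    percolation_every: int = 1           # compute lambda_c on every k-th pair
    m_permutations: int = 10_000
    n_boot: int = 300


@dataclass
class EventSummary:
    """Per-acquisition statistics; the row format of the cross-swarm table."""

    event_id: str
    species: str
    n: float                  # median group size over used frames
    r1: float                 # mean nearest-neighbour distance, m
    body_length: float        # m
    r1_over_bl: float
    polarization: float
    polarization_sd: float
    rotational: float
    rotational_sd: float
    dilatational: float
    dilatational_sd: float
    r0: float                 # mean first zero of C(r), m (NaN if never found)
    chi: float
    chi_sd: float
    lambda_c: float           # mean percolation threshold, m
    frames_used: int
    frames_skipped: int


def analyze_event(
    traj,
    config: AnalysisConfig | None = None,
    event_id: str | None = None,
    species: str | None = None,
    body_length: float | None = None,
) -> EventSummary:
    """Full per-event chain on a trajectory or simulation run.

    ``traj`` must expose ``frame_pairs()`` and ``fps`` (a
    :class:`~midgeswarm.io.SwarmTrajectory` or a simulator
    :class:`~midgeswarm.simulators.SimulationRun`).  Frames the mode
    decomposition cannot handle are skipped and counted.
    """
    cfg = config or AnalysisConfig()
    bl = body_length if body_length is not None else getattr(traj, "body_length", None)
    if bl is None or bl <= 0:
        raise EventRejected("missing body-length metadata")
    eid = event_id or getattr(traj, "event_id", "") or "event"
    spc = species or getattr(traj, "species_label", "")
    stats = frame_pair_statistics(traj, cfg.bin_width)
    used = [s for s in stats if not s["skipped"]]
    n_skipped = len(stats) - len(used)
    if len(used) < 2:
        raise EventRejected(
            f"{eid}: fewer than 2 usable frame pairs ({len(used)} usable, {n_skipped} skipped)"
        )
    ops, r1s, lambdas, ns = [], [], [], []
    pair_iter = list(traj.frame_pairs())
    usable_idx = {s["time_index"] for s in used}
    for k, (fa, fb) in enumerate(pair_iter):
        if fa.time_index not in usable_idx:
            continue
        try:
            ops.append(order_parameters(fa, fb, traj.fps))
        except DegenerateFrameError:
            continue
        r1s.append(nearest_neighbour_distance(fa))
        ns.append(fa.n)
        if k % cfg.percolation_every == 0:
            lambdas.append(
                percolation_threshold(fa.positions, cfg.percolation_theta).threshold
            )
    chis = np.array([s["chi"] for s in used])
    r0s = np.array([s["r0"] for s in used if s["r0"] is not None], float)
    if len(r0s) == 0:
        logger.info("%s: correlation function never crossed zero", eid)

    def mstats(vals):
        vals = np.asarray(vals, float)
        vals = vals[np.isfinite(vals)]
        if len(vals) == 0:
            return float("nan"), float("nan")
        sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        return float(vals.mean()), sd

    pol, pol_sd = mstats([o.polarization for o in ops])
    rot, rot_sd = mstats([o.rotational for o in ops])
    dil, dil_sd = mstats([o.dilatational for o in ops])
    r1 = float(np.mean(r1s))
    return EventSummary(
        event_id=eid,
        species=spc,
        n=float(np.median(ns)),
        r1=r1,
        body_length=float(bl),
        r1_over_bl=r1 / bl,
        polarization=pol,
        polarization_sd=pol_sd,
        rotational=rot,
        rotational_sd=rot_sd,
        dilatational=dil,
        dilatational_sd=dil_sd,
        r0=float(np.mean(r0s)) if len(r0s) else float("nan"),
        chi=float(chis.mean()),
        chi_sd=float(chis.std(ddof=1)),
        lambda_c=float(np.mean(lambdas)) if lambdas else float("nan"),
        frames_used=len(used),
        frames_skipped=n_skipped,
    )


def cross_event_report(
    summaries: list[EventSummary],
    config: AnalysisConfig | None = None,
    seed: int = 0,
) -> dict:
    """Metric-interaction report across events.

    Runs the permutation comparison of χ against r1/BL vs r1, the critical
    scaling fit on (r1/BL, χ), the percolation slope fit on (r1, λc), and
    combines transition point and slope into the interaction-range
    estimate.  Pieces that fail on the given events (e.g. no disordered
    branch) are reported as such rather than aborting the report.
    """
    cfg = config or AnalysisConfig()
    if len(summaries) < 5:
        raise ValueError("cross-event report needs at least 5 events")
    r1 = np.array([s.r1 for s in summaries])
    bl = np.array([s.body_length for s in summaries])
    chi = np.array([s.chi for s in summaries])
    lam = np.array([s.lambda_c for s in summaries])
    report: dict = {
        "n_events": len(summaries),
        "events": [asdict(s) for s in summaries],
    }
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(3)]
    test_bl, test_raw = compare_scaling_variables(
        r1, bl, chi, m=cfg.m_permutations, seed=seeds[0]
    )
    report["metric_test"] = {
        "p_r1_over_bl": test_bl.p_value,
        "rho_r1_over_bl": test_bl.rho,
        "p_r1": test_raw.p_value,
        "rho_r1": test_raw.rho,
    }
    fit = None
    if test_bl.p_value > 0.05 or test_bl.rho >= 0:
        # no significant decrease of chi with r1/BL: fitting a divergence
        # to such events would manufacture a transition out of noise
        report["scaling_fit"] = {
            "error": "no significant decreasing dependence of chi on r1/BL "
            f"(rho = {test_bl.rho:.2f}, P = {test_bl.p_value:.3f})"
        }
    else:
        try:
            # x = r1/BL is a positive ratio: constrain the divergence to x_c >= 0
            fit = fit_critical_scaling(
                r1 / bl, chi, n_boot=cfg.n_boot, seed=seeds[1], x_c_min=0.0
            )
            report["scaling_fit"] = {
                "amplitude": fit.amplitude,
                "x_c": fit.x_c,
                "gamma": fit.gamma,
                "ci": {k: list(v) for k, v in fit.ci.items()},
            }
        except (InvalidBranchError, NonIdentifiableError, ValueError) as exc:
            report["scaling_fit"] = {"error": f"{type(exc).__name__}: {exc}"}
    ok_lam = np.isfinite(lam)
    if ok_lam.sum() >= 3:
        s_slope, ci_s = threshold_scaling(
            list(zip(r1[ok_lam], lam[ok_lam])), seed=seeds[2]
        )
        report["percolation_slope"] = {"s": s_slope, "ci": list(ci_s)}
    else:
        report["percolation_slope"] = {"error": "fewer than 3 events with lambda_c"}
        s_slope = None
    if fit is not None and s_slope is not None and fit.x_c > 0:
        rc_bl, ci_rc = estimate_interaction_range(
            fit.x_c, s_slope, ci_xc=tuple(fit.ci["x_c"]), ci_s=ci_s
        )
        report["interaction_range_bl"] = {"rc_over_bl": rc_bl, "ci": list(ci_rc)}
    else:
        report["interaction_range_bl"] = {
            "error": "transition point or percolation slope unavailable"
        }
    return report


def order_parameter_table(traj: SwarmTrajectory, null_samples: int = 200, seed: int = 0):
    """Per-frame order parameters plus the uncorrelated-system band.

    Returns a pandas DataFrame with columns (frame, polarization,
    rotational, dilatational, null_mean_*, null_sd_*) mirroring the
    time-series panels of the per-event figures.
    """
    import pandas as pd

    from .modes import null_band

    rows = []
    for fa, fb in traj.frame_pairs():
        try:
            op = order_parameters(fa, fb, traj.fps)
        except DegenerateFrameError:
            continue
        rows.append(
            {
                "frame": fa.time_index,
                "n": fa.n,
                "polarization": op.polarization,
                "rotational": op.rotational,
                "dilatational": op.dilatational,
            }
        )
    table = pd.DataFrame(rows)
    if len(table):
        band = null_band(int(table["n"].median()), null_samples, seed)
        for key, (mean, sd) in band.items():
            table[f"null_mean_{key}"] = mean
            table[f"null_sd_{key}"] = sd
    return table
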