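"""Collective-mode subtraction and order parameters.

A swarm's instantaneous motion is decomposed into three collective modes —
rigid translation, optimal rigid rotation, and uniform dilatation
(expansion/contraction) — which are subtracted sequentially from the
individual velocities.  What remains, the residual fluctuation ``δv_i``, is
the individual's deviation from every group-level motion and is the raw
material of the correlation analysis.  The dimensionless fluctuation

    φ_i = δv_i / sqrt((1/N) Σ_k |δv_k|²)

satisfies (1/N) Σ φ_i·φ_i = 1 by construction, which pins the normalization
of the connected correlation function and forces its cumulative version to
−1 at infinite range.

Order parameters quantify how much of the motion *is* collective:

* polarization Φ — modulus of the mean unit velocity (translational order);
* rotational order R — coherence of angular momenta about the fitted
  rotation axis;
* dilatational order Λ — mean cosine between the rotation-subtracted
  fluctuation and the radial direction (+1 coherent expansion, −1
  contraction).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .io import SwarmFrame

_MIN_ROTATION_N = 3


class DegenerateFrameError(ValueError):
    """Frame geometry too degenerate for the requested fit."""


@dataclass
class ModeDecomposition:
    """Result of subtracting the three collective modes from one frame pair."""

    v_cm: np.ndarray            # centre-of-mass velocity (3,), m/s
    rotation: np.ndarray        # 3x3 proper orthogonal matrix
    rotation_axis: np.ndarray   # unit vector, angle about it is >= 0
    rotation_angle: float       # radians, in [0, pi]
    dilatation: float           # scalar alpha per frame step (dimensionless)
    y: np.ndarray               # (N, 3) centre-of-mass-frame positions, m
    dv_translation: np.ndarray  # (N, 3) velocity minus v_cm, m/s
    dv_rotation: np.ndarray     # (N, 3) after translation+rotation subtraction
    residuals: np.ndarray       # (N, 3) delta-v after all three modes, m/s
    phi: np.ndarray             # (N, 3) dimensionless fluctuations

    @property
    def n(self) -> int:
        return self.y.shape[0]


@dataclass
class OrderParameters:
    """The three scalar order parameters of one frame pair.

    ``rotational`` and ``dilatational`` are NaN when the frame is too small
    (N < 4) for a well-posed rotation fit.
    """

    polarization: float
    rotational: float
    dilatational: float
    n_excluded: int = 0


def _pair_arrays(frame_a: SwarmFrame, frame_b: SwarmFrame):
    """Index-aligned (pos_t, pos_next, vel) with NaN-velocity rows dropped."""
    if frame_a.velocities is None:
        raise DegenerateFrameError("first frame carries no velocities")
    if frame_a.positions.shape != frame_b.positions.shape:
        raise DegenerateFrameError("frame pair must share one id set")
    ok = np.all(np.isfinite(frame_a.velocities), axis=1)
    return frame_a.positions[ok], frame_b.positions[ok], frame_a.velocities[ok]


def subtract_translation(pos: np.ndarray, vel: np.ndarray):
    """Centre-of-mass frame positions and translation-subtracted velocities.

    Returns ``(y, dv)`` with ``y_i = x_i − x_cm`` and ``dv_i = v_i − V``;
    ``Σ dv_i = 0`` holds to round-off.
    """
    pos = np.asarray(pos, float)
    vel = np.asarray(vel, float)
    if pos.shape[0] < 2:
        raise DegenerateFrameError("translation subtraction needs N >= 2")
    y = pos - pos.mean(axis=0)
    dv = vel - vel.mean(axis=0)
    return y, dv


def fit_rotation(y_t: np.ndarray, y_next: np.ndarray):
    """Optimal proper rotation mapping ``y_t`` onto ``y_next`` about the origin.

    Least-squares superposition: returns the orthogonal matrix ``R`` with
    ``det R = +1`` minimizing ``Σ_i |y_next,i − R y_t,i|²``, together with
    the rotation axis (unit vector; the angle about it is non-negative).

    Raises
    ------
    DegenerateFrameError
        For N < 3 or (near-)collinear configurations, where the rotation is
        not uniquely determined.
    """
    y_t = np.asarray(y_t, float)
    y_next = np.asarray(y_next, float)
    if y_t.shape[0] < _MIN_ROTATION_N:
        raise DegenerateFrameError("rotation fit needs N >= 3")
    cov = y_next.T @ y_t
    s = np.linalg.svd(cov, compute_uv=False)
    scale = s[0] if s[0] > 0 else 1.0
    if s[1] / scale < 1e-12:
        raise DegenerateFrameError("collinear configuration: rotation fit rank-deficient")
    rot, _ = Rotation.align_vectors(y_next, y_t)
    rotvec = rot.as_rotvec()
    angle = float(np.linalg.norm(rotvec))
    axis = rotvec / angle if angle > 0 else np.array([0.0, 0.0, 1.0])
    return rot.as_matrix(), axis, angle


def fit_dilatation(y_rot: np.ndarray, y_next: np.ndarray) -> float:
    """Optimal uniform scale: alpha minimizing Σ_i |y_next,i − α y_rot,i|².

    Closed form ``α = (Σ y_rot,i·y_next,i) / (Σ |y_rot,i|²)``.
    """
    y_rot = np.asarray(y_rot, float)
    denom = float(np.sum(y_rot * y_rot))
    if denom == 0.0:
        raise DegenerateFrameError("all positions at the origin: dilatation undefined")
    return float(np.sum(y_rot * np.asarray(y_next, float)) / denom)


def decompose(frame_a: SwarmFrame, frame_b: SwarmFrame, fps: float) -> ModeDecomposition:
    """Subtract translation, rotation and dilatation from one frame pair.

    The collective-mode velocity of individual *i* over one frame step is
    ``V + fps·(α R y_i − y_i)``; the residual is ``δv_i = v_i`` minus that.
    ``Σ δv_i = 0`` and ``(1/N) Σ φ_i·φ_i = 1`` hold to round-off (the φ are
    set to zero in the measure-zero case of exactly vanishing residuals).
    """
    pos_t, pos_next, vel = _pair_arrays(frame_a, frame_b)
    y, dv = subtract_translation(pos_t, vel)
    y_next = pos_next - pos_next.mean(axis=0)
    rot, axis, angle = fit_rotation(y, y_next)
    y_rotated = y @ rot.T
    alpha = fit_dilatation(y_rotated, y_next)
    v_cm = vel.mean(axis=0)
    dv_rot = dv - fps * (y_rotated - y)
    residuals = dv - fps * (alpha * y_rotated - y)
    mean_sq = float(np.mean(np.sum(residuals**2, axis=1)))
    # residuals that are pure round-off of an exact collective motion must
    # not be inflated to an O(1) fluctuation field by the normalization
    v_scale = float(np.mean(np.sum(vel**2, axis=1)))
    negligible = mean_sq <= 1e-24 * max(v_scale, 1e-300)
    phi = (
        np.zeros_like(residuals)
        if negligible
        else residuals / np.sqrt(mean_sq)
    )
    return ModeDecomposition(
        v_cm=v_cm,
        rotation=rot,
        rotation_axis=axis,
        rotation_angle=angle,
        dilatation=alpha,
        y=y,
        dv_translation=dv,
        dv_rotation=dv_rot,
        residuals=residuals,
        phi=phi,
    )


def polarization(vel: np.ndarray) -> tuple[float, int]:
    """Modulus of the mean unit velocity; zero-speed rows are excluded."""
    vel = np.asarray(vel, float)
    speed = np.linalg.norm(vel, axis=1)
    ok = speed > 0
    n_excluded = int(np.sum(~ok))
    if n_excluded:
        warnings.warn(f"polarization: excluded {n_excluded} zero-speed individuals")
    if not np.any(ok):
        raise DegenerateFrameError("all speeds zero: polarization undefined")
    units = vel[ok] / speed[ok, None]
    return float(np.linalg.norm(units.mean(axis=0))), n_excluded


def rotational_order(y: np.ndarray, dv: np.ndarray, axis: np.ndarray) -> float:
    """Coherence of angular momenta about the rotation axis.

    For each individual the angular momentum of its translation-subtracted
    velocity about the axis is ``L_i = y_⊥i × dv_i`` (``y_⊥`` the position
    component orthogonal to the axis); ``m_i = (L_i·K̂)/|L_i| ∈ [−1, 1]``
    and the order parameter is ``|mean m_i|``, 1 for a coherent rigid
    rotation and ~1/√N for incoherent motion.
    """
    axis = np.asarray(axis, float)
    y_perp = y - np.outer(y @ axis, axis)
    ell = np.cross(y_perp, dv)
    norm = np.linalg.norm(ell, axis=1)
    ok = norm > 0
    if not np.any(ok):
        return float("nan")
    m = (ell[ok] @ axis) / norm[ok]
    return float(abs(m.mean()))


def dilatational_order(y: np.ndarray, dv_rot: np.ndarray) -> float:
    """Mean cosine between rotation-subtracted fluctuation and radial direction.

    +1 for coherent expansion, −1 for coherent contraction, ~0 otherwise.
    """
    ny = np.linalg.norm(y, axis=1)
    ndv = np.linalg.norm(dv_rot, axis=1)
    ok = (ny > 0) & (ndv > 0)
    if not np.any(ok):
        return float("nan")
    cosines = np.sum(y[ok] * dv_rot[ok], axis=1) / (ny[ok] * ndv[ok])
    return float(cosines.mean())


def order_parameters(frame_a: SwarmFrame, frame_b: SwarmFrame, fps: float) -> OrderParameters:
    """Polarization, rotational and dilatational order of one frame pair.

    R and Λ need the rotation fit and are reported as NaN for N < 4.
    """
    pos_t, _, vel = _pair_arrays(frame_a, frame_b)
    phi_pol, n_excluded = polarization(vel)
    if pos_t.shape[0] < 4:
        return OrderParameters(phi_pol, float("nan"), float("nan"), n_excluded)
    dec = decompose(frame_a, frame_b, fps)
    r = rotational_order(dec.y, dec.dv_translation, dec.rotation_axis)
    lam = dilatational_order(dec.y, dec.dv_rotation)
    return OrderParameters(phi_pol, r, lam, n_excluded)


def _random_unit_vectors(n: int, rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def null_band(N: int, n_samples: int, seed: int | np.random.Generator) -> dict:
    """Monte-Carlo mean/sd of each order parameter for an uncorrelated system.

    Draws ``n_samples`` synthetic frames of N independent uniformly random
    unit velocities (and uniform-in-ball positions for R and Λ) and measures
    the same statistics the data path measures.  E[Φ] ~ sqrt(8/(3πN)) for
    large N.
    """
    if N < 2:
        raise ValueError("null band needs N >= 2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    stats = {"polarization": [], "rotational": [], "dilatational": []}
    for _ in range(n_samples):
        units = _random_unit_vectors(N, rng)
        stats["polarization"].append(np.linalg.norm(units.mean(axis=0)))
        pos = rng.normal(size=(N, 3))
        pos *= (rng.uniform(size=(N, 1)) ** (1 / 3)) / np.linalg.norm(pos, axis=1, keepdims=True)
        y = pos - pos.mean(axis=0)
        dv = units - units.mean(axis=0)
        axis = _random_unit_vectors(1, rng)[0]
        stats["rotational"].append(rotational_order(y, dv, axis))
        stats["dilatational"].append(dilatational_order(y, dv))
    return {
        k: (float(np.mean(v)), float(np.std(v, ddof=1)))
        for k, v in stats.items()
    }
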