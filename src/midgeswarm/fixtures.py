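"""Synthetic swarm generators with known ground truth.

Each generator emits data with exactly the statistical structure one stage
of the analysis assumes, together with the planted truth, so recovery tests
are self-contained:

* :func:`planted_mode_swarm` — a frame pair whose motion is a known
  translation + rotation + dilatation plus re-centred Gaussian residuals;
* :func:`correlated_swarm` — a single frame with a direction-fluctuation
  field of tunable correlation length (common unit vector per spatial blob
  plus isotropic noise, then re-centred and normalized);
* :func:`correlated_trajectory` — a multi-frame trajectory whose step
  displacements carry such a correlated field, for the time-series
  estimators;
* :func:`poisson_swarm` — uniform (Poisson) points in a cube at a given
  density, for the percolation stage.

All generators are deterministic given (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import SwarmFrame, SwarmTrajectory
from .modes import _random_unit_vectors


def _rng(seed: int | np.random.Generator) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _uniform_ball(n: int, radius: float, rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    return radius * v * rng.uniform(size=(n, 1)) ** (1 / 3)


def _axis_angle_matrix(axis: np.ndarray, angle: float) -> np.ndarray:
    from scipy.spatial.transform import Rotation

    axis = np.asarray(axis, float)
    return Rotation.from_rotvec(angle * axis / np.linalg.norm(axis)).as_matrix()


@dataclass
class FixtureSpec:
    """Planted-mode swarm parameters (units: metres, m/s, radians)."""

    n: int = 50
    radius: float = 0.5
    v_cm: np.ndarray = field(default_factory=lambda: np.array([0.1, 0.0, 0.0]))
    rotation_axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    rotation_angle: float = 0.1
    dilatation: float = 1.0
    noise_sd: float = 0.0      # m/s, sd of the residual velocity field
    fps: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be non-negative")


def planted_mode_swarm(spec: FixtureSpec):
    """Frame pair with known collective modes.

    The second frame is a translated, rotated and dilated copy of the first
    plus iid Gaussian residual displacements re-centred to sum zero, so the
    planted values are exactly the least-squares optima at zero noise.

    Returns ``(frame_a, frame_b, truth)`` with velocities attached to
    ``frame_a`` and ``truth`` holding the planted modes and residuals.
    """
    s = spec
    rng = _rng(s.seed)
    pos = _uniform_ball(s.n, s.radius, rng)
    center = rng.normal(scale=s.radius, size=3)
    x_t = center + pos
    rot = _axis_angle_matrix(s.rotation_axis, s.rotation_angle)
    eps = rng.normal(scale=s.noise_sd, size=(s.n, 3))
    eps -= eps.mean(axis=0)
    y = pos - pos.mean(axis=0)
    dt = 1.0 / s.fps
    x_next = x_t.mean(axis=0) + s.v_cm * dt + s.dilatation * (y @ rot.T) + eps * dt
    vel = (x_next - x_t) / dt
    ids = np.arange(s.n)
    frame_a = SwarmFrame(0, x_t, ids, vel)
    frame_b = SwarmFrame(1, x_next, ids, None)
    truth = {
        "v_cm": s.v_cm + eps.mean(axis=0),  # zero-mean residuals: == planted v_cm
        "rotation": rot,
        "rotation_axis": np.asarray(s.rotation_axis, float)
        / np.linalg.norm(s.rotation_axis),
        "rotation_angle": s.rotation_angle,
        "dilatation": s.dilatation,
        "residuals": eps,
    }
    return frame_a, frame_b, truth


def correlated_phi(
    positions: np.ndarray,
    corr_length: float,
    noise_sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Correlated dimensionless fluctuation field on given positions.

    Spatial blobs of radius ``corr_length`` share a common random unit
    vector; isotropic Gaussian noise of sd ``noise_sd`` is added, the field
    is re-centred (Σφ = 0) and scaled so (1/N)Σ|φ|² = 1.  ``corr_length``
    → 0 degenerates to an uncorrelated field.
    """
    positions = np.asarray(positions, float)
    n = positions.shape[0]
    if corr_length <= 0:
        phi = rng.normal(size=(n, 3))
    else:
        # greedy blob centres at spacing ~corr_length, then nearest-centre labels
        order = rng.permutation(n)
        centres = []
        for i in order:
            p = positions[i]
            if all(np.linalg.norm(p - c) > corr_length for c in centres):
                centres.append(p)
        centres = np.array(centres)
        d = np.linalg.norm(positions[:, None, :] - centres[None, :, :], axis=2)
        labels = np.argmin(d, axis=1)
        blob_vec = _random_unit_vectors(len(centres), rng)
        phi = blob_vec[labels] + rng.normal(scale=noise_sd, size=(n, 3))
    phi = phi - phi.mean(axis=0)
    ms = np.mean(np.sum(phi**2, axis=1))
    return phi / np.sqrt(ms)


def correlated_swarm(
    n: int = 200,
    radius: float = 0.5,
    corr_length: float = 0.15,
    noise_sd: float = 0.3,
    seed: int | np.random.Generator = 0,
):
    """Single frame with a planted correlation length.

    Returns ``(positions, phi, truth)``; ``truth['corr_length']`` is the
    planted blob radius.
    """
    rng = _rng(seed)
    positions = _uniform_ball(n, radius, rng)
    phi = correlated_phi(positions, corr_length, noise_sd, rng)
    return positions, phi, {"corr_length": corr_length, "radius": radius}


def correlated_trajectory(
    n: int = 100,
    radius: float = 0.5,
    corr_length: float = 0.15,
    noise_sd: float = 0.3,
    n_frames: int = 12,
    speed: float = 0.02,
    fps: float = 1.0,
    body_length: float = 0.002,
    seed: int | np.random.Generator = 0,
    event_id: str = "synthetic",
) -> SwarmTrajectory:
    """Trajectory whose per-step displacement field has correlation length L.

    Each step displaces individual i by ``speed·φ_i/fps`` with a fresh
    correlated field φ (no collective modes planted), producing a
    positionally quasi-static swarm with spatially correlated velocity
    fluctuations — the structure the susceptibility estimators target.
    With ``corr_length = 0`` the same construction yields an uncorrelated
    control.
    """
    rng = _rng(seed)
    pos = _uniform_ball(n, radius, rng)
    ids = np.arange(n)
    frames = [SwarmFrame(0, pos.copy(), ids)]
    for t in range(1, n_frames):
        phi = correlated_phi(pos, corr_length, noise_sd, rng)
        pos = pos + speed * phi / fps
        frames.append(SwarmFrame(t, pos.copy(), ids))
    from .io import compute_velocities

    return compute_velocities(
        SwarmTrajectory(frames, fps=fps, body_length=body_length, event_id=event_id)
    )


def poisson_swarm(
    n: int, density: float, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Uniform points in a cube with ``n/side³ = density`` (units: metres)."""
    if density <= 0:
        raise ValueError("density must be positive")
    rng = _rng(seed)
    side = (n / density) ** (1 / 3)
    return rng.uniform(0.0, side, size=(n, 3))
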