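"""Generative models: non-interacting harmonic swarm and 3D Vicsek model.

Two simulators bracket the data analysis:

* the **Non-interacting Harmonic Swarm (NHS)** — independent Langevin
  particles in a 3D harmonic trap, integrated with the Euler scheme.  It
  looks like a swarm (particles mill around a fixed point) but carries no
  interaction, hence no connected correlation: it is the null baseline for
  C(r) and the susceptibility.
* the **Vicsek model in a central potential** — self-propelled particles at
  fixed speed aligning with all metric neighbours within a radius ``rc``,
  with a harmonic pull toward the origin providing cohesion (open
  boundaries).  Scanning the confinement strength moves the rescaled
  nearest-neighbour distance x = r1/rc across the order–disorder
  transition, reproducing the coexistence of disorder and large
  correlation near the transition.

Both are bit-reproducible given (config, seed).  Sampled output exposes the
same ``frame_pairs()`` / ``fps`` interface as field trajectories, so the
identical estimator code analyses simulations and data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numba
import numpy as np

from .io import SwarmFrame, nearest_neighbour_distance
from .modes import polarization


class StabilityError(RuntimeError):
    """Integrator parameters outside the stable regime, or state diverged."""


class BracketingError(RuntimeError):
    """A scan did not bracket the feature (peak) it was asked to locate."""


@dataclass
class NHSConfig:
    """Parameters of the non-interacting harmonic swarm (Langevin/Euler).

    ``m dv = (−γ v − k x) dt + σ √dt ξ`` per particle and component, with
    ``σ = sqrt(2 γ T)`` so the stationary positional variance per component
    is ``T/k``.  Default friction is the critically damped value
    ``γ = 2 sqrt(m k)``; the default step is 0.01 of the natural period
    scale ``sqrt(m/k)``.
    """

    n: int = 100
    mass: float = 1.0
    spring_k: float = 1.0
    friction: float | None = None     # None -> critically damped
    temperature: float = 1.0
    dt: float = 0.01
    steps: int = 20_000
    transient: int = 5_000
    sample_every: int = 100
    seed: int = 0
    init_scale: float | None = None   # None -> stationary sqrt(T/k)

    def __post_init__(self) -> None:
        if self.friction is None:
            self.friction = 2.0 * np.sqrt(self.mass * self.spring_k)
        for name in ("n", "mass", "spring_k", "friction", "temperature", "dt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class VicsekConfig:
    """Parameters of the 3D Vicsek model with harmonic attraction.

    Per step each particle averages the velocities of all particles within
    ``rc`` (itself included), subtracts ``beta·x_i`` (the central force),
    normalizes, applies a random rotation uniform over the spherical cap of
    solid angle ``4π·eta`` around that direction, and moves at speed ``v0``
    with unit time step.  ``beta = 0`` recovers the standard Vicsek model.
    """

    n: int = 256
    v0: float = 0.05
    rc: float = 1.0
    eta: float = 0.15
    beta: float = 2e-4
    steps: int = 15_000
    transient: int = 4_000
    sample_every: int = 200   # spacing chosen to decorrelate fluctuation samples
    n_samples: int = 50
    seed: int = 0
    init_radius: float | None = None  # None -> rc * n**(1/3)

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if self.rc <= 0 or self.v0 <= 0:
            raise ValueError("rc and v0 must be positive")
        if not 0.0 <= self.eta <= 1.0:
            raise ValueError("eta must lie in [0, 1]")
        if self.beta < 0:
            raise ValueError("beta must be non-negative")
        if self.transient + self.n_samples * self.sample_every > self.steps:
            raise ValueError("steps too few for the requested sampling protocol")


@dataclass
class SimulationRun:
    """Sampled output of a simulator, analysable like a field trajectory.

    Each sample is a consecutive state pair ``(x(t), x(t+Δ))``; velocities
    are the finite differences over that step, matching the convention used
    for field data.
    """

    config: object
    positions_t: np.ndarray      # (n_samples, N, 3)
    positions_next: np.ndarray   # (n_samples, N, 3)
    fps: float                   # 1/Δ of the sampled step
    body_length: float = 1.0

    @property
    def n_samples(self) -> int:
        return self.positions_t.shape[0]

    def frame_pairs(self) -> Iterator[tuple[SwarmFrame, SwarmFrame]]:
        n = self.positions_t.shape[1]
        ids = np.arange(n)
        for k in range(self.n_samples):
            vel = (self.positions_next[k] - self.positions_t[k]) * self.fps
            yield (
                SwarmFrame(2 * k, self.positions_t[k], ids, vel),
                SwarmFrame(2 * k + 1, self.positions_next[k], ids, None),
            )

    def mean_r1(self) -> float:
        return float(
            np.mean([nearest_neighbour_distance(p) for p in self.positions_t])
        )

    def mean_polarization(self) -> tuple[float, float]:
        phis = []
        for k in range(self.n_samples):
            vel = (self.positions_next[k] - self.positions_t[k]) * self.fps
            phis.append(polarization(vel)[0])
        return float(np.mean(phis)), float(np.std(phis, ddof=1))


def simulate_nhs(config: NHSConfig) -> SimulationRun:
    """Integrate the NHS Langevin equation; sample consecutive state pairs.

    Raises :class:`StabilityError` when ``γ·dt/m >= 2`` (Euler unstable for
    the velocity relaxation) or the state stops being finite.
    """
    c = config
    if c.friction * c.dt / c.mass >= 2.0:
        raise StabilityError("Euler step too large: friction*dt/mass >= 2")
    rng = np.random.default_rng(c.seed)
    sigma = np.sqrt(2.0 * c.friction * c.temperature)
    # start at the stationary law so the transient is a formality
    x_scale = (
        c.init_scale if c.init_scale is not None
        else np.sqrt(c.temperature / c.spring_k)
    )
    x = rng.normal(scale=x_scale, size=(c.n, 3))
    v = rng.normal(scale=np.sqrt(c.temperature / c.mass), size=(c.n, 3))
    sample_at = set(
        range(c.transient, c.steps - 1, c.sample_every)
    )
    pos_t, pos_next = [], []
    pending = False
    for step in range(c.steps):
        if pending:
            pos_next.append(x.copy())
            pending = False
        if step in sample_at:
            pos_t.append(x.copy())
            pending = True
        noise = rng.standard_normal((c.n, 3))
        v = v + (c.dt * (-c.friction * v - c.spring_k * x) + sigma * np.sqrt(c.dt) * noise) / c.mass
        x = x + v * c.dt
        if not np.isfinite(x).all():
            raise StabilityError(f"non-finite state at step {step}")
    if pending:
        pos_next.append(x.copy())
    return SimulationRun(
        config=c,
        positions_t=np.array(pos_t),
        positions_next=np.array(pos_next),
        fps=1.0 / c.dt,
    )


@numba.njit(cache=True)
def _vicsek_loop(pos, vel, rc2, eta, beta, v0, n_steps, record_at, out_t, out_next, seed):  # pragma: no cover - compiled
    np.random.seed(seed)
    n = pos.shape[0]
    new_dir = np.empty((n, 3))
    rec = 0
    for step in range(n_steps):
        recording = rec < record_at.shape[0] and record_at[rec] == step
        if recording:
            for i in range(n):
                for d in range(3):
                    out_t[rec, i, d] = pos[i, d]
        # alignment: average velocity of all metric neighbours (self included)
        for i in range(n):
            sx = 0.0
            sy = 0.0
            sz = 0.0
            cnt = 0
            for j in range(n):
                dx = pos[j, 0] - pos[i, 0]
                dy = pos[j, 1] - pos[i, 1]
                dz = pos[j, 2] - pos[i, 2]
                if dx * dx + dy * dy + dz * dz < rc2:
                    sx += vel[j, 0]
                    sy += vel[j, 1]
                    sz += vel[j, 2]
                    cnt += 1
            sx = sx / cnt - beta * pos[i, 0]
            sy = sy / cnt - beta * pos[i, 1]
            sz = sz / cnt - beta * pos[i, 2]
            norm = np.sqrt(sx * sx + sy * sy + sz * sz)
            if norm == 0.0:
                # isotropic fallback for the measure-zero cancellation case
                sx, sy, sz = np.random.normal(), np.random.normal(), np.random.normal()
                norm = np.sqrt(sx * sx + sy * sy + sz * sz)
            dx0, dy0, dz0 = sx / norm, sy / norm, sz / norm
            # random rotation uniform on the spherical cap of solid angle 4*pi*eta
            cosa = 1.0 - 2.0 * eta * np.random.random()
            sina = np.sqrt(max(0.0, 1.0 - cosa * cosa))
            phi = 2.0 * np.pi * np.random.random()
            # orthonormal basis perpendicular to the mean direction
            if abs(dx0) < 0.9:
                e1x, e1y, e1z = 0.0, -dz0, dy0
            else:
                e1x, e1y, e1z = -dz0, 0.0, dx0
            e1n = np.sqrt(e1x * e1x + e1y * e1y + e1z * e1z)
            e1x, e1y, e1z = e1x / e1n, e1y / e1n, e1z / e1n
            e2x = dy0 * e1z - dz0 * e1y
            e2y = dz0 * e1x - dx0 * e1z
            e2z = dx0 * e1y - dy0 * e1x
            cp, sp = np.cos(phi), np.sin(phi)
            new_dir[i, 0] = cosa * dx0 + sina * (cp * e1x + sp * e2x)
            new_dir[i, 1] = cosa * dy0 + sina * (cp * e1y + sp * e2y)
            new_dir[i, 2] = cosa * dz0 + sina * (cp * e1z + sp * e2z)
        for i in range(n):
            for d in range(3):
                vel[i, d] = v0 * new_dir[i, d]
                pos[i, d] = pos[i, d] + vel[i, d]
        if recording:
            for i in range(n):
                for d in range(3):
                    out_next[rec, i, d] = pos[i, d]
            rec += 1
    return rec


def simulate_vicsek(config: VicsekConfig) -> SimulationRun:
    """Run the Vicsek model; sample ``n_samples`` consecutive state pairs.

    Sampling starts after ``transient`` steps at intervals of
    ``sample_every``; each sample records the positions immediately before
    and after one update, so finite differencing recovers the exact
    velocities.
    """
    c = config
    rng = np.random.default_rng(c.seed)
    r_init = c.init_radius if c.init_radius is not None else c.rc * c.n ** (1 / 3)
    pos = rng.normal(size=(c.n, 3))
    pos *= r_init * (rng.uniform(size=(c.n, 1)) ** (1 / 3)) / np.linalg.norm(
        pos, axis=1, keepdims=True
    )
    dirs = rng.normal(size=(c.n, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    vel = c.v0 * dirs
    record_at = np.arange(c.transient, c.transient + c.n_samples * c.sample_every, c.sample_every)
    out_t = np.empty((c.n_samples, c.n, 3))
    out_next = np.empty((c.n_samples, c.n, 3))
    numba_seed = int(rng.integers(0, 2**31 - 1))
    recorded = _vicsek_loop(
        pos.copy(), vel.copy(), c.rc**2, c.eta, c.beta, c.v0,
        int(record_at[-1]) + 1, record_at, out_t, out_next, numba_seed,
    )
    if recorded != c.n_samples:
        raise StabilityError("sampling protocol failed to record all samples")
    if not (np.isfinite(out_t).all() and np.isfinite(out_next).all()):
        raise StabilityError("non-finite Vicsek state")
    return SimulationRun(config=c, positions_t=out_t, positions_next=out_next, fps=1.0)


def _chi_per_sample(run: SimulationRun, bin_width: float | None = None) -> np.ndarray:
    from .correlation import frame_pair_statistics

    stats = frame_pair_statistics(run, bin_width)
    return np.array([s["chi"] for s in stats if not s["skipped"]])


def nhs_baseline_chi(
    config: NHSConfig, bin_width: float | None = None
) -> tuple[float, float]:
    """Mean and sd of χ over NHS samples — the non-interacting benchmark.

    The full decomposition → φ → χ chain is applied to the simulated
    frames, exactly as for field data.
    """
    chis = _chi_per_sample(simulate_nhs(config), bin_width)
    return float(chis.mean()), float(chis.std(ddof=1))


def _is_stationary(r1_series: np.ndarray, max_rel_drift: float = 0.2) -> bool:
    """Crude drift check: linear trend over the window below a fraction of the mean."""
    t = np.arange(len(r1_series))
    slope = np.polyfit(t, r1_series, 1)[0]
    return abs(slope) * len(r1_series) <= max_rel_drift * r1_series.mean()


@dataclass
class ScanRow:
    control: float
    x: float                 # r1 / rc
    r1: float
    phi_mean: float
    phi_sd: float
    chi_mean: float
    chi_sd: float
    stationary: bool


def scan_vicsek(
    base: VicsekConfig,
    control_values: Sequence[float],
    control: str = "beta",
    bin_width: float | None = None,
    seed: int | None = None,
) -> list[ScanRow]:
    """One Vicsek run per control value; measure x = r1/rc, Φ and χ.

    ``control`` is the config field varied (``beta`` tunes density, ``n``
    system size).  Φ and χ come from the same estimator code paths used on
    field data.  Rows failing the stationarity drift check are flagged,
    not dropped.
    """
    from dataclasses import replace

    rows = []
    ss = np.random.SeedSequence(base.seed if seed is None else seed)
    run_seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(len(control_values))]
    for value, run_seed in zip(control_values, run_seeds):
        cfg = replace(base, **{control: type(getattr(base, control))(value)}, seed=run_seed)
        run = simulate_vicsek(cfg)
        r1_series = np.array(
            [nearest_neighbour_distance(p) for p in run.positions_t]
        )
        phi_mean, phi_sd = run.mean_polarization()
        chis = _chi_per_sample(run, bin_width)
        rows.append(
            ScanRow(
                control=float(value),
                x=float(r1_series.mean() / cfg.rc),
                r1=float(r1_series.mean()),
                phi_mean=phi_mean,
                phi_sd=phi_sd,
                chi_mean=float(chis.mean()),
                chi_sd=float(chis.std(ddof=1)),
                stationary=_is_stationary(r1_series),
            )
        )
    return rows


def finite_size_scaling(
    scans_by_size: dict[int, Sequence[ScanRow]]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Locate the χ peak of each size's scan: returns (sizes, x_max, chi_max).

    The peak must be bracketed: a maximum sitting on either end of a scan
    raises :class:`BracketingError`.
    """
    sizes, x_max, chi_max = [], [], []
    for n, rows in sorted(scans_by_size.items()):
        rows = sorted(rows, key=lambda r: r.x)
        chis = np.array([r.chi_mean for r in rows])
        k = int(np.argmax(chis))
        if k == 0 or k == len(rows) - 1:
            raise BracketingError(
                f"size {n}: susceptibility peak at scan boundary (index {k})"
            )
        sizes.append(n)
        x_max.append(rows[k].x)
        chi_max.append(chis[k])
    return np.array(sizes), np.array(x_max), np.array(chi_max)
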