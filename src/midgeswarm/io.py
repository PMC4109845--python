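"""Trajectory containers and plain-text I/O.

A swarm acquisition is a time-ordered stack of frames, each holding the 3D
positions (metres) of the identified individuals.  Velocities are derived by
forward finite differences at the acquisition frame rate; the last frame
therefore carries no velocity and is excluded from per-frame statistics.

Two text dialects are supported:

* trajectory CSV with header ``frame,id,x,y,z`` (metres), and
* two-column pairwise files (distance in metres, dimensionless scalar
  product of two normalized velocity fluctuations), the dialect of the
  published supplementary data files.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd


class TrajectoryError(ValueError):
    """Malformed or inconsistent trajectory input."""


@dataclass
class SwarmFrame:
    """Positions (and, once derived, velocities) of N individuals at one instant.

    Attributes
    ----------
    time_index : int
        0-based frame index; physical time is ``time_index / fps``.
    positions : (N, 3) ndarray
        Positions in metres.
    ids : (N,) ndarray
        Individual identifiers, index-aligned with ``positions``.
    velocities : (N, 3) ndarray or None
        Forward-difference velocities in m/s; rows may be NaN for
        individuals absent from the next frame.
    """

    time_index: int
    positions: np.ndarray
    ids: np.ndarray
    velocities: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.ids = np.asarray(self.ids)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise TrajectoryError("positions must be an (N, 3) array")
        if self.positions.shape[0] < 1:
            raise TrajectoryError("a frame needs at least one individual")
        if not np.all(np.isfinite(self.positions)):
            raise TrajectoryError(f"non-finite position in frame {self.time_index}")
        if len(self.ids) != len(self.positions):
            raise TrajectoryError("ids and positions must be index-aligned")
        if self.velocities is not None:
            self.velocities = np.asarray(self.velocities, dtype=float)
            if self.velocities.shape != self.positions.shape:
                raise TrajectoryError("velocities must align with positions")

    @property
    def n(self) -> int:
        return self.positions.shape[0]


@dataclass
class SwarmTrajectory:
    """An acquisition: ordered frames plus experimental metadata."""

    frames: list[SwarmFrame]
    fps: float
    body_length: float
    species_label: str = ""
    event_id: str = ""

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise TrajectoryError("fps must be positive")
        if self.body_length <= 0:
            raise TrajectoryError("body_length must be positive")
        idx = [f.time_index for f in self.frames]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise TrajectoryError("frame indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self) -> Iterator[SwarmFrame]:
        return iter(self.frames)

    def frame_pairs(self) -> Iterator[tuple[SwarmFrame, SwarmFrame]]:
        """Consecutive frame pairs restricted to individuals present in both.

        Yields pairs of frames whose rows are index-aligned on the common id
        set (tracking gaps are dropped, not interpolated).  Velocities, when
        present on the first frame, are subset accordingly.
        """
        for a, b in zip(self.frames, self.frames[1:]):
            common, ia, ib = np.intersect1d(a.ids, b.ids, return_indices=True)
            if len(common) == 0:
                continue
            va = None if a.velocities is None else a.velocities[ia]
            yield (
                SwarmFrame(a.time_index, a.positions[ia], common, va),
                SwarmFrame(b.time_index, b.positions[ib], common, None),
            )


@dataclass(frozen=True)
class PairwiseSample:
    """One pair of individuals: mutual distance and fluctuation dot product."""

    distance: float
    dot: float

    def __post_init__(self) -> None:
        if self.distance < 0:
            raise ValueError("distance must be non-negative")
        if not np.isfinite(self.dot):
            raise ValueError("dot product must be finite")


def load_trajectory(
    path: str | Path,
    fps: float,
    body_length: float,
    species_label: str = "",
    event_id: str = "",
) -> SwarmTrajectory:
    """Read a ``frame,id,x,y,z`` delimited table into a :class:`SwarmTrajectory`.

    Raises
    ------
    TrajectoryError
        On a malformed row (with its line number) or a duplicated
        ``(frame, id)`` pair.
    """
    path = Path(path)
    try:
        table = pd.read_csv(path)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise TrajectoryError(f"{path}: cannot parse trajectory table: {exc}") from exc
    required = ["frame", "id", "x", "y", "z"]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise TrajectoryError(f"{path}: missing columns {missing}")
    for col in ("frame", "x", "y", "z"):
        coerced = pd.to_numeric(table[col], errors="coerce")
        bad = coerced.isna() & table[col].notna()
        if bad.any():
            # +2: header line plus 1-based numbering
            line = int(bad.idxmax()) + 2
            raise TrajectoryError(f"{path}: non-numeric '{col}' at line {line}")
        if coerced.isna().any():
            line = int(coerced.isna().idxmax()) + 2
            raise TrajectoryError(f"{path}: empty '{col}' at line {line}")
        table[col] = coerced
    dup = table.duplicated(subset=["frame", "id"])
    if dup.any():
        line = int(dup.idxmax()) + 2
        raise TrajectoryError(f"{path}: duplicate (frame, id) at line {line}")
    frames = []
    for t, grp in table.sort_values(["frame", "id"]).groupby("frame", sort=True):
        frames.append(
            SwarmFrame(
                time_index=int(t),
                positions=grp[["x", "y", "z"]].to_numpy(float),
                ids=grp["id"].to_numpy(),
            )
        )
    return SwarmTrajectory(frames, fps=fps, body_length=body_length,
                           species_label=species_label, event_id=event_id)


def write_trajectory(traj: SwarmTrajectory, path: str | Path) -> None:
    """Write the ``frame,id,x,y,z`` dialect read by :func:`load_trajectory`."""
    rows = []
    for f in traj.frames:
        for i in range(f.n):
            rows.append((f.time_index, f.ids[i], *f.positions[i]))
    pd.DataFrame(rows, columns=["frame", "id", "x", "y", "z"]).to_csv(
        Path(path), index=False
    )


def compute_velocities(traj: SwarmTrajectory) -> SwarmTrajectory:
    """Attach forward-difference velocities ``v_i(t) = (x_i(t+1) - x_i(t)) * fps``.

    Individuals absent at ``t + 1`` get NaN velocity at ``t`` and are
    excluded from downstream per-frame statistics; the final frame carries
    no velocity.
    """
    if len(traj.frames) < 2:
        raise TrajectoryError("need at least two frames to differentiate")
    steps = np.diff([f.time_index for f in traj.frames])
    if not np.all(steps == steps[0]):
        raise TrajectoryError("frame spacing must be constant")
    dt = steps[0] / traj.fps
    new_frames: list[SwarmFrame] = []
    for a, b in zip(traj.frames, traj.frames[1:]):
        vel = np.full_like(a.positions, np.nan)
        common, ia, ib = np.intersect1d(a.ids, b.ids, return_indices=True)
        vel[ia] = (b.positions[ib] - a.positions[ia]) / dt
        new_frames.append(replace(a, velocities=vel))
    new_frames.append(replace(traj.frames[-1], velocities=None))
    return replace(traj, frames=new_frames)


def nearest_neighbour_distance(frame_or_positions: SwarmFrame | np.ndarray) -> float:
    """Mean distance of each individual to its nearest neighbour (r1, metres)."""
    pos = (
        frame_or_positions.positions
        if isinstance(frame_or_positions, SwarmFrame)
        else np.asarray(frame_or_positions, dtype=float)
    )
    if pos.shape[0] < 2:
        raise TrajectoryError("nearest-neighbour distance needs N >= 2")
    from scipy.spatial import cKDTree

    d, _ = cKDTree(pos).query(pos, k=2)
    return float(d[:, 1].mean())


def read_pairwise(path: str | Path) -> list[PairwiseSample]:
    """Read a two-column pairwise file (distance m, dimensionless dot product).

    Whitespace- or comma-delimited; row order is preserved.  An empty file
    yields an empty list.
    """
    path = Path(path)
    samples: list[PairwiseSample] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            text = raw.strip()
            if not text:
                continue
            parts = text.replace(",", " ").split()
            if len(parts) < 2:
                raise TrajectoryError(f"{path}: line {lineno}: expected two columns")
            try:
                r, c = float(parts[0]), float(parts[1])
            except ValueError as exc:
                raise TrajectoryError(
                    f"{path}: line {lineno}: non-numeric value"
                ) from exc
            samples.append(PairwiseSample(distance=r, dot=c))
    return samples


def write_pairwise(samples: Sequence[PairwiseSample], path: str | Path) -> None:
    with open(Path(path), "w") as fh:
        for s in samples:
            fh.write(f"{s.distance:.9g} {s.dot:.9g}\n")
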