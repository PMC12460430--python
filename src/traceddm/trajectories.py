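"""Cursor-trajectory data model, I/O, and preprocessing.

A trajectory is one trial's time-stamped cursor path during the stimulus
phase of a two-alternative forced-choice task: samples ``(t, x, y)`` in
seconds and screen pixels, recorded at roughly 107 Hz.  Preprocessing
centers every trajectory to a common horizontal start (``x[0] = 0``) and
mirrors right-response trajectories to the left, so that all paths end on
the negative x side and deviation measures share one sign convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Iterator, List, Literal

import numpy as np
import pandas as pd

__all__ = [
    "Trajectory",
    "TrialRecord",
    "TrialSet",
    "KinematicSeries",
    "SchemaError",
    "ConsistencyError",
    "DegenerateTrajectoryError",
    "load_trials",
    "preprocess",
    "kinematics",
]

Side = Literal["left", "right"]

TRAJECTORY_COLUMNS = ["participant", "trial", "t", "x", "y"]
TRIAL_COLUMNS = [
    "participant",
    "trial",
    "stimulus_side",
    "response_side",
    "accuracy",
    "rt",
]


class SchemaError(ValueError):
    """An input table is missing a required column or has a bad dtype."""


class ConsistencyError(ValueError):
    """Trial table and trajectory table disagree about which trials exist."""


class DegenerateTrajectoryError(ValueError):
    """A trajectory is too short (or otherwise degenerate) for an operation."""


@dataclass(frozen=True)
class Trajectory:
    """One trial's cursor path: time (s), x (px), y (px).

    ``t`` must be strictly increasing with ``t[0] >= 0``; all three arrays
    share a common length of at least 2.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        if not (t.shape == x.shape == y.shape) or t.ndim != 1:
            raise ValueError("t, x, y must be equal-length 1-D sequences")
        if t.size < 2:
            raise DegenerateTrajectoryError(
                f"trajectory needs >= 2 samples, got {t.size}"
            )
        if not np.all(np.isfinite(t)) or not np.all(np.isfinite(x)) or not np.all(
            np.isfinite(y)
        ):
            raise ValueError("non-finite values in trajectory")
        if t[0] < 0:
            raise ValueError("timestamps must start at >= 0")
        if np.any(np.diff(t) <= 0):
            raise ValueError("timestamps not increasing")

    def __len__(self) -> int:
        return int(self.t.size)

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])


@dataclass(frozen=True)
class TrialRecord:
    """Trial metadata joined to its trajectory."""

    participant_id: str
    trial_index: int
    stimulus_side: Side
    response_side: Side
    accuracy: int
    rt: float
    trajectory: Trajectory

    def __post_init__(self) -> None:
        if self.stimulus_side not in ("left", "right"):
            raise ValueError(f"bad stimulus_side {self.stimulus_side!r}")
        if self.response_side not in ("left", "right"):
            raise ValueError(f"bad response_side {self.response_side!r}")
        expected = int(self.response_side == self.stimulus_side)
        if int(self.accuracy) != expected:
            raise ValueError(
                "accuracy must equal (response_side == stimulus_side); "
                f"got accuracy={self.accuracy} for response={self.response_side}, "
                f"stimulus={self.stimulus_side}"
            )
        if not (0.0 < self.rt <= 2.0 + 1e-9):
            raise ValueError(f"rt must lie in (0, 2] s, got {self.rt}")


@dataclass
class TrialSet:
    """Trials grouped by participant; trial_index unique per participant."""

    trials: Dict[str, List[TrialRecord]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pid, recs in self.trials.items():
            if len(recs) == 0:
                raise ValueError(f"participant {pid!r} has no trials")
            idx = [r.trial_index for r in recs]
            if len(set(idx)) != len(idx):
                raise ValueError(f"duplicate trial_index for participant {pid!r}")

    @property
    def participants(self) -> List[str]:
        return list(self.trials.keys())

    def n_trials(self, participant_id: str) -> int:
        return len(self.trials[participant_id])

    def __iter__(self) -> Iterator[TrialRecord]:
        for recs in self.trials.values():
            yield from recs

    def __len__(self) -> int:
        return sum(len(v) for v in self.trials.values())

    def map_trajectories(self, fn) -> "TrialSet":
        """Return a new TrialSet with ``fn(record)`` replacing each trajectory."""
        out: Dict[str, List[TrialRecord]] = {}
        for pid, recs in self.trials.items():
            out[pid] = [replace(r, trajectory=fn(r)) for r in recs]
        return TrialSet(out)

    def preprocessed(self) -> "TrialSet":
        """Center and mirror every trajectory (see :func:`preprocess`)."""
        return self.map_trajectories(
            lambda r: preprocess(r.trajectory, r.response_side)
        )

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Long-format trajectory frame and per-trial metadata frame."""
        traj_rows = []
        trial_rows = []
        for rec in self:
            n = len(rec.trajectory)
            traj_rows.append(
                pd.DataFrame(
                    {
                        "participant": [rec.participant_id] * n,
                        "trial": [rec.trial_index] * n,
                        "t": rec.trajectory.t,
                        "x": rec.trajectory.x,
                        "y": rec.trajectory.y,
                    }
                )
            )
            trial_rows.append(
                {
                    "participant": rec.participant_id,
                    "trial": rec.trial_index,
                    "stimulus_side": rec.stimulus_side,
                    "response_side": rec.response_side,
                    "accuracy": rec.accuracy,
                    "rt": rec.rt,
                }
            )
        return pd.concat(traj_rows, ignore_index=True), pd.DataFrame(trial_rows)


@dataclass(frozen=True)
class KinematicSeries:
    """Step-wise speed and acceleration derived from a trajectory.

    ``speed[i]`` is the Euclidean displacement between samples ``i`` and
    ``i+1`` divided by the step duration; the step is attributed to the later
    endpoint, ``t_mid[i] = t[i+1]``.  ``accel`` is the finite difference of
    speed over ``t_mid`` (one element shorter).
    """

    t_mid: np.ndarray
    speed: np.ndarray
    accel: np.ndarray
    dt: np.ndarray  # per-step durations, same length as speed

    def __post_init__(self) -> None:
        if self.speed.size != self.t_mid.size or self.accel.size != self.speed.size - 1:
            raise ValueError("inconsistent kinematic series lengths")


def preprocess(traj: Trajectory, response_side: Side) -> Trajectory:
    """Center x to 0 at the start and mirror right-response paths to the left.

    Idempotent for already-centered left-response trajectories; y and t are
    untouched.
    """
    if len(traj) < 2:  # pragma: no cover - Trajectory already enforces this
        raise DegenerateTrajectoryError("trajectory needs >= 2 samples")
    x = traj.x - traj.x[0]
    if response_side == "right":
        x = -x
    elif response_side != "left":
        raise ValueError(f"bad response_side {response_side!r}")
    return Trajectory(t=traj.t, x=x, y=traj.y)


def kinematics(traj: Trajectory) -> KinematicSeries:
    """Per-step Euclidean speed and its finite-difference acceleration."""
    dt = np.diff(traj.t)
    if np.any(dt == 0):
        raise ValueError("duplicate timestamps: zero-length step")
    disp = np.hypot(np.diff(traj.x), np.diff(traj.y))
    speed = disp / dt
    t_mid = traj.t[1:]
    if speed.size >= 2:
        accel = np.diff(speed) / np.diff(t_mid)
    else:
        accel = np.empty(0)
    return KinematicSeries(t_mid=t_mid, speed=speed, accel=accel, dt=dt)


def _require_columns(df: pd.DataFrame, cols: List[str], name: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{name} is missing column(s): {', '.join(missing)}")


def load_trials(
    trajectory_file: str | Path,
    trial_file: str | Path,
    *,
    time_unit: str = "s",
    flip_y: bool = False,
) -> TrialSet:
    """Read long-format trajectory CSV and per-trial CSV into a TrialSet.

    Parameters
    ----------
    time_unit : "s" or "ms"; trajectory timestamps are converted to seconds.
    flip_y : negate y at load time for recordings whose screen y-axis grows
        downward, so that y increases toward the response boxes.
    """
    traj_df = pd.read_csv(trajectory_file)
    trial_df = pd.read_csv(trial_file)
    _require_columns(traj_df, TRAJECTORY_COLUMNS, "trajectory file")
    _require_columns(trial_df, TRIAL_COLUMNS, "trial file")
    if time_unit not in ("s", "ms"):
        raise ValueError(f"time_unit must be 's' or 'ms', got {time_unit!r}")

    for col in ("t", "x", "y"):
        if not np.issubdtype(traj_df[col].dtype, np.number):
            raise SchemaError(f"trajectory column {col!r} is not numeric")
    traj_df = traj_df.dropna(subset=["t", "x", "y"])
    scale = 1e-3 if time_unit == "ms" else 1.0

    grouped = {
        key: g for key, g in traj_df.groupby(["participant", "trial"], sort=False)
    }
    trials: Dict[str, List[TrialRecord]] = {}
    for row in trial_df.itertuples(index=False):
        key = (row.participant, row.trial)
        if key not in grouped:
            raise ConsistencyError(
                f"trial {row.trial} of participant {row.participant!r} has no "
                "trajectory rows"
            )
        g = grouped[key]
        t = g["t"].to_numpy(dtype=float) * scale
        y = g["y"].to_numpy(dtype=float)
        if flip_y:
            y = -y
        traj = Trajectory(t=t, x=g["x"].to_numpy(dtype=float), y=y)
        rec = TrialRecord(
            participant_id=str(row.participant),
            trial_index=int(row.trial),
            stimulus_side=str(row.stimulus_side),
            response_side=str(row.response_side),
            accuracy=int(row.accuracy),
            rt=float(row.rt),
            trajectory=traj,
        )
        trials.setdefault(rec.participant_id, []).append(rec)
    return TrialSet(trials)
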