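"""The 18 per-trial cursor measures and their participant-level aggregation.

All measures assume a preprocessed trajectory: x centered to 0 at the start
and mirrored so the chosen response box lies to the left (final x <= 0).
Under that convention the "alternative response" side is the positive-x side,
which fixes the sign of the deviation measures (MADabove, minX).

Measure families
----------------
* deviation from the straight start-to-end chord: AD, AUC, MAD, MADabove,
  minX, curvature;
* kinematics of the step-wise Euclidean speed: maxVel, meanVel, minVel,
  maxAcc, timeToPeakVel, timeToPeakAcc, motionTime, motorPauses;
* discrete event counts: xFlips, reversals, accChanges;
* complexity: sampleEnX, the sample entropy of the first-differenced
  x series.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import _wfpt
from .trajectories import (
    KinematicSeries,
    Trajectory,
    TrialRecord,
    TrialSet,
    kinematics,
)

__all__ = [
    "MEASURE_NAMES",
    "MeasureConfig",
    "deviation_measures",
    "kinematic_measures",
    "count_measures",
    "sample_entropy",
    "sample_entropy_x",
    "compute_all",
    "aggregate",
    "trial_measures_frame",
]

#: Canonical column order for the 18 measures (field-standard short names).
MEASURE_NAMES = [
    "accChanges",
    "AD",
    "AUC",
    "curvature",
    "MAD",
    "MADabove",
    "maxAcc",
    "maxVel",
    "meanVel",
    "minVel",
    "minX",
    "motorPauses",
    "motionTime",
    "reversals",
    "sampleEnX",
    "timeToPeakAcc",
    "timeToPeakVel",
    "xFlips",
]


@dataclass(frozen=True)
class MeasureConfig:
    """Tunables of the measure extraction.

    sampen_m : embedding dimension of the sample entropy (templates of this
        length are compared).
    sampen_r_frac : tolerance as a fraction of the SD of the differenced
        x series.
    pause_threshold : displacement (px) at or below which a step counts as a
        motor pause; 0 means strictly frozen cursor.
    """

    sampen_m: int = 2
    sampen_r_frac: float = 0.2
    pause_threshold: float = 0.0


class UndefinedDeviationError(ValueError):
    """Chord has zero length; perpendicular deviation is undefined."""


def deviation_measures(traj: Trajectory) -> Dict[str, float]:
    """AD, AUC, MAD, MADabove, minX, curvature relative to the straight chord.

    The signed perpendicular deviation is positive on the side of the
    non-chosen (right) alternative.  AD averages absolute deviations; AUC is
    the absolute net area between path and chord (trapezoid rule over the
    chord-projection coordinate); minX is the largest x attained, i.e. the
    closest horizontal approach to the alternative side.
    """
    p0 = np.array([traj.x[0], traj.y[0]])
    p1 = np.array([traj.x[-1], traj.y[-1]])
    chord_vec = p1 - p0
    chord = float(np.hypot(*chord_vec))
    if chord == 0.0:
        raise UndefinedDeviationError("start and end coincide: zero chord length")
    d = chord_vec / chord
    dx = traj.x - p0[0]
    dy = traj.y - p0[1]
    # cross((dx, dy), d): positive toward the alternative (right) side for a
    # leftward-up chord.
    dev = dx * d[1] - dy * d[0]
    proj = dx * d[0] + dy * d[1]
    steps = np.hypot(np.diff(traj.x), np.diff(traj.y))
    path_len = float(steps.sum())
    pos = dev[dev > 0]
    return {
        "AD": float(np.mean(np.abs(dev))),
        "AUC": float(abs(np.trapezoid(dev, proj))),
        "MAD": float(np.max(np.abs(dev))),
        "MADabove": float(np.max(pos)) if pos.size else 0.0,
        "minX": float(np.max(traj.x)),
        "curvature": path_len / chord,
    }


def kinematic_measures(
    traj: Trajectory,
    kin: Optional[KinematicSeries] = None,
    *,
    pause_threshold: float = 0.0,
) -> Dict[str, float]:
    """Velocity/acceleration summaries and the motion/pause time split.

    Peak times use the FIRST maximum and are measured from stimulus onset
    (t = 0), with each step attributed to its later endpoint.  meanVel is
    time-weighted: total path length over total duration.
    """
    if len(traj) < 3:
        raise ValueError("kinematic measures need >= 3 samples")
    if kin is None:
        kin = kinematics(traj)
    duration = traj.duration
    disp = kin.speed * kin.dt
    pause_mask = disp <= pause_threshold
    motor_pauses = float(kin.dt[pause_mask].sum())
    i_v = int(np.argmax(kin.speed))  # argmax returns the first maximum
    i_a = int(np.argmax(kin.accel))
    return {
        "maxVel": float(kin.speed[i_v]),
        "meanVel": float(disp.sum() / duration),
        "minVel": float(kin.speed.min()),
        "maxAcc": float(kin.accel[i_a]),
        "timeToPeakVel": float(kin.t_mid[i_v]),
        "timeToPeakAcc": float(kin.t_mid[1 + i_a]),
        "motorPauses": motor_pauses,
        "motionTime": duration - motor_pauses,
    }


def _sign_changes(values: np.ndarray) -> int:
    """Sign changes across consecutive nonzero entries (zero runs skipped).

    Entries within a tiny relative tolerance of zero count as zero so that
    floating-point residue from the finite differences cannot manufacture
    events.
    """
    if values.size == 0:
        return 0
    tol = 1e-9 * max(1.0, float(np.max(np.abs(values))))
    s = np.sign(np.where(np.abs(values) <= tol, 0.0, values))
    s = s[s != 0]
    if s.size < 2:
        return 0
    return int(np.count_nonzero(s[:-1] != s[1:]))


def count_measures(traj: Trajectory, kin: Optional[KinematicSeries] = None) -> Dict[str, float]:
    """xFlips, reversals (midline traversals), and acceleration sign changes.

    A reversal is a crossing of the vertical line through the starting
    x position after the first departure from it; touching the line and
    returning to the same side counts once.
    """
    if kin is None:
        kin = kinematics(traj)
    xflips = _sign_changes(np.diff(traj.x))

    rel = traj.x - traj.x[0]
    s = np.sign(rel)
    reversals = 0
    state = 0.0  # side currently occupied; 0 until first departure
    touched = False  # on the midline after having departed
    for si in s:
        if si == 0.0:
            if state != 0.0:
                touched = True
            continue
        if state == 0.0:
            state = si
        elif si != state:
            reversals += 1
            state = si
        elif touched:
            # left the line back to the same side: the touch counts once
            reversals += 1
        touched = False

    acc_changes = _sign_changes(kin.accel) if kin.accel.size else 0
    return {
        "xFlips": float(xflips),
        "reversals": float(reversals),
        "accChanges": float(acc_changes),
    }


def sample_entropy(series: np.ndarray, m: int = 2, r: float | None = None,
                   r_frac: float = 0.2) -> float:
    """SampEn(m, r) of a 1-D series with Chebyshev distance, self-matches excluded.

    B counts matching template pairs of length m, A of length m+1, both over
    the first ``n - m`` starting positions so the counts are comparable.
    Returns ``-ln(A/B)``; 0 when A == B > 0; NaN when B == 0 (no structure to
    compare, flagged missing).
    """
    z = np.asarray(series, dtype=float)
    n = z.size
    if n < m + 2:
        raise ValueError(f"series too short for SampEn: n={n}, m={m}")
    if r is None:
        sd = float(np.std(z, ddof=0))
        r = r_frac * sd
    b, a = _wfpt.sampen_counts(np.ascontiguousarray(z), m, float(r))
    if b == 0:
        return float("nan")
    if a == 0:
        return float("nan")
    return float(-math.log(a / b))


def sample_entropy_x(traj: Trajectory, m: int = 2, r_frac: float = 0.2) -> float:
    """Sample entropy of the first-differenced x series (movement complexity)."""
    dx = np.diff(traj.x)
    return sample_entropy(dx, m=m, r_frac=r_frac)


def compute_all(trial: TrialRecord, config: MeasureConfig = MeasureConfig(),
                *, preprocessed: bool = False) -> Dict[str, float]:
    """All 18 measures for one trial; errors surface as NaN cells, never drops.

    ``preprocessed=False`` (default) centers/mirrors the trajectory first.
    """
    from .trajectories import preprocess

    traj = trial.trajectory if preprocessed else preprocess(
        trial.trajectory, trial.response_side
    )
    out: Dict[str, float] = {name: float("nan") for name in MEASURE_NAMES}
    kin = kinematics(traj)
    try:
        out.update(deviation_measures(traj))
    except UndefinedDeviationError:
        pass
    try:
        out.update(kinematic_measures(traj, kin, pause_threshold=config.pause_threshold))
    except ValueError:
        pass
    out.update(count_measures(traj, kin))
    try:
        out["sampleEnX"] = sample_entropy_x(traj, m=config.sampen_m,
                                            r_frac=config.sampen_r_frac)
    except ValueError:
        pass
    return out


def trial_measures_frame(trials: TrialSet,
                         config: MeasureConfig = MeasureConfig()) -> pd.DataFrame:
    """One row per trial: participant, trial, rt, accuracy + the 18 measures."""
    rows: List[dict] = []
    for rec in trials:
        m = compute_all(rec, config)
        rows.append(
            {
                "participant": rec.participant_id,
                "trial": rec.trial_index,
                "rt": rec.rt,
                "accuracy": rec.accuracy,
                **{k: m[k] for k in MEASURE_NAMES},
            }
        )
    return pd.DataFrame(rows)


def aggregate(trials: TrialSet,
              config: MeasureConfig = MeasureConfig()) -> pd.DataFrame:
    """Participant-level means of the 18 measures plus mean rt and accuracy.

    Correct and error trials are both retained; every measure is averaged
    over the same trial subset (NaN cells propagate so a missing measure is
    visible rather than silently imputed).
    """
    per_trial = trial_measures_frame(trials, config)
    grouped = per_trial.drop(columns=["trial"]).groupby("participant", sort=False)
    out = grouped.mean()
    out["n_trials"] = grouped.size()
    return out.reset_index()
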