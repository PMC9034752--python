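"""Reach-kinematics preprocessing.

Movement onset/end are defined by a 10%-of-peak-speed threshold; the movement
direction is the signed angle (counterclockwise positive) between the
origin-to-target vector and the origin-to-hand vector at target distance,
with the hand position at target distance obtained by linear interpolation
between the samples straddling that radius.  Trials are excluded when the
radial distance is not strictly increasing after first exceeding 0.4 cm or
when the reach never gets within 95% of the target distance (7.6 cm).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .epochs import assign_epoch_column
from .synthetic_data import TrialRecord

__all__ = [
    "KinematicSummary",
    "detect_bounds",
    "movement_direction",
    "reaction_time",
    "apply_exclusions",
    "summarize_trial",
    "summarize_experiment",
    "assign_epochs",
]

EXCLUSION_REASONS = ("none", "non_monotonic", "short_reach")


@dataclass
class KinematicSummary:
    subject_id: str
    trial_index: int
    onset_ms: float
    end_ms: float
    peak_speed_cm_s: float
    movement_direction_deg: float
    reaction_time_ms: float
    valid: bool
    exclusion_reason: str
    movement_time_flag: bool = False  # exceeded the 500 ms criterion (flagged, not excluded)
    rt_negative_flag: bool = False


def _as_trajectory(traj) -> np.ndarray:
    arr = np.asarray(traj, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise ValueError("trajectory must have shape (n_samples, 3): t_ms, x_cm, y_cm")
    if arr.shape[0] < 3:
        raise ValueError("trajectory needs at least 3 samples")
    if np.any(np.diff(arr[:, 0]) <= 0):
        raise ValueError("trajectory timestamps must be strictly increasing")
    return arr


def _speeds(traj: np.ndarray, smooth_ms: float = 0.0) -> np.ndarray:
    """Speed (cm/s) by central finite differences of position.

    Optional boxcar smoothing of the position (window ``smooth_ms``) before
    differentiating; off by default.
    """
    t = traj[:, 0] / 1000.0  # seconds
    xy = traj[:, 1:3]
    if smooth_ms > 0:
        dt_ms = np.median(np.diff(traj[:, 0]))
        w = max(int(round(smooth_ms / dt_ms)), 1)
        if w > 1:
            kernel = np.ones(w) / w
            pad = w // 2
            padded = np.pad(xy, ((pad, w - 1 - pad), (0, 0)), mode="edge")
            xy = np.column_stack([np.convolve(padded[:, j], kernel, mode="valid")
                                  for j in range(2)])
    vx = np.gradient(xy[:, 0], t)
    vy = np.gradient(xy[:, 1], t)
    return np.hypot(vx, vy)


def detect_bounds(trajectory, smooth_ms: float = 0.0) -> tuple[float, float, float]:
    """Movement onset, end and peak speed from the 10%-of-peak threshold.

    Onset is the first sample whose speed reaches 10% of the trial's peak
    speed; end is the first sample after the peak whose speed falls below
    that threshold (the last sample if speed never does).
    """
    traj = _as_trajectory(trajectory)
    speed = _speeds(traj, smooth_ms=smooth_ms)
    peak_idx = int(np.argmax(speed))
    peak = float(speed[peak_idx])
    if peak <= 0:
        raise ValueError("degenerate trajectory: zero speed throughout")
    thresh = 0.10 * peak
    onset_idx = int(np.argmax(speed >= thresh))  # first crossing
    after = speed[peak_idx + 1:]
    below = np.nonzero(after < thresh)[0]
    end_idx = peak_idx + 1 + int(below[0]) if below.size else len(speed) - 1
    return float(traj[onset_idx, 0]), float(traj[end_idx, 0]), peak


def _wrap_angle(deg: float) -> float:
    """Normalize to (-180, 180]."""
    wrapped = (deg + 180.0) % 360.0 - 180.0
    return 180.0 if wrapped == -180.0 else wrapped


def movement_direction(trajectory, target_angle_deg: float,
                       target_distance_cm: float = 8.0) -> float:
    """Signed hand deviation (deg, CCW positive) at target distance.

    The hand position at target distance is linearly interpolated between the
    two samples straddling the radius; the returned angle is the hand angle
    minus the target angle, wrapped to (-180, 180], i.e. directions are
    reported after rotating to a common axis with the target at 0 deg.
    """
    traj = _as_trajectory(trajectory)
    r = np.hypot(traj[:, 1], traj[:, 2])
    beyond = np.nonzero(r >= target_distance_cm)[0]
    if beyond.size == 0:
        raise ValueError("trajectory never reaches target distance; exclude first")
    j = int(beyond[0])
    if j == 0:
        x, y = traj[0, 1], traj[0, 2]
    else:
        i = j - 1
        frac = (target_distance_cm - r[i]) / (r[j] - r[i])
        x = traj[i, 1] + frac * (traj[j, 1] - traj[i, 1])
        y = traj[i, 2] + frac * (traj[j, 2] - traj[i, 2])
    hand_angle = np.degrees(np.arctan2(y, x))
    return _wrap_angle(float(hand_angle) - float(target_angle_deg))


def reaction_time(trajectory, target_onset_ms: float, smooth_ms: float = 0.0) -> float:
    """Time from target appearance to movement onset (may be negative; not clipped)."""
    onset_ms, _, _ = detect_bounds(trajectory, smooth_ms=smooth_ms)
    return onset_ms - float(target_onset_ms)


def apply_exclusions(trajectory, *, monotone_tol_cm: float = 0.01,
                     min_distance_cm: float = 7.6,
                     onset_radius_cm: float = 0.4) -> tuple[bool, str]:
    """Exclusion rules: non-monotonic radial progress, or a too-short reach.

    A trial is invalid if, after the hand first exceeds ``onset_radius_cm``
    from the origin, the radial distance decreases by more than
    ``monotone_tol_cm`` between consecutive samples, or if the maximum radial
    distance stays below ``min_distance_cm``.  The tolerance guards against
    floating-point/sensor jitter; 0 reproduces the literal strictly-increasing
    rule.
    """
    traj = _as_trajectory(trajectory)
    r = np.hypot(traj[:, 1], traj[:, 2])
    past = np.nonzero(r > onset_radius_cm)[0]
    if past.size:
        seg = r[past[0]:]
        if np.any(np.diff(seg) < -monotone_tol_cm):
            return False, "non_monotonic"
    if r.max() < min_distance_cm:
        return False, "short_reach"
    return True, "none"


def summarize_trial(record: TrialRecord, *, target_distance_cm: float = 8.0,
                    movement_time_limit_ms: float = 500.0,
                    smooth_ms: float = 0.0,
                    monotone_tol_cm: float = 0.01) -> KinematicSummary:
    """Full per-trial kinematic summary (bounds, direction, RT, exclusions)."""
    traj = record.trajectory
    if traj is None:
        raise ValueError("trial has no trajectory; use the trial-level dialect instead")
    valid, reason = apply_exclusions(traj, monotone_tol_cm=monotone_tol_cm,
                                     min_distance_cm=0.95 * target_distance_cm)
    onset, end, peak = detect_bounds(traj, smooth_ms=smooth_ms)
    rt = onset - record.target_onset_ms
    if valid:
        direction = movement_direction(traj, record.target_angle_deg, target_distance_cm)
    else:
        r = np.hypot(np.asarray(traj)[:, 1], np.asarray(traj)[:, 2])
        # report direction at target distance when reachable, else at max extent
        try:
            direction = movement_direction(traj, record.target_angle_deg, target_distance_cm)
        except ValueError:
            direction = movement_direction(traj, record.target_angle_deg, float(r.max()))
    return KinematicSummary(
        subject_id=record.subject_id, trial_index=record.trial_index,
        onset_ms=onset, end_ms=end, peak_speed_cm_s=peak,
        movement_direction_deg=direction, reaction_time_ms=rt,
        valid=valid, exclusion_reason=reason,
        movement_time_flag=(end - onset) > movement_time_limit_ms,
        rt_negative_flag=rt < 0)


def summarize_experiment(records: Iterable[TrialRecord], **kwargs) -> pd.DataFrame:
    """Per-trial KinematicSummary table for a collection of trial records."""
    rows = []
    for rec in records:
        s = summarize_trial(rec, **kwargs)
        rows.append({
            "subject_id": rec.subject_id, "group": rec.group_label,
            "phase": rec.phase, "trial": rec.trial_index,
            "target_deg": rec.target_angle_deg,
            "onset_ms": s.onset_ms, "end_ms": s.end_ms,
            "peak_speed_cm_s": s.peak_speed_cm_s,
            "movement_direction_deg": s.movement_direction_deg,
            "reaction_time_ms": s.reaction_time_ms,
            "valid": s.valid, "exclusion_reason": s.exclusion_reason,
            "movement_time_flag": s.movement_time_flag,
        })
    return pd.DataFrame(rows)


def assign_epochs(trial_table: pd.DataFrame) -> pd.DataFrame:
    """Label each trial with its epoch type (EpochedTable).

    Input: a trial-level table with ``subject_id``, ``group``, ``phase``,
    ``trial`` and ``movement_direction_deg`` (a ``valid`` column is honoured
    and defaults to all-valid).  Excluded trials keep their epoch label but
    carry ``valid=False`` so the model stage can drop them; epochs with
    exclusions are left short rather than re-binned.
    """
    df = trial_table.copy()
    df["epoch"] = assign_epoch_column(df)
    if "valid" not in df.columns:
        df["valid"] = True
    cols = ["subject_id", "group", "epoch", "trial", "movement_direction_deg", "valid"]
    extra = [c for c in ("phase",) if c in df.columns]
    return df[cols + extra]
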