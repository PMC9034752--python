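"""Synthetic visuomotor rotation experiments.

Generates complete experiments — reach trajectories plus metadata — with the
statistical structure the downstream analysis assumes: a four-phase design
(baseline, 30 deg clockwise rotation, no-feedback aftereffect, washout), a
saturating implicit learning curve produced by a single-rate state-space
learner plus an explicit re-aiming component, a small counterclockwise
baseline bias, between-subject parameter variability, and trial-level motor
noise.

Sign convention: angles are in degrees, counterclockwise positive, with the
target rotated to 0 deg.  The clockwise cursor rotation displaces the cursor
to -30 deg relative to the hand, so learning drives the hand direction toward
+30 deg.

The learner updates its implicit state from the cursor error of the *planned*
movement (rotation minus implicit minus explicit components); trial noise and
the static perceptual bias do not enter the update, so the baseline offset
persists through baseline and washout.  During the aftereffect phase the
explicit component is removed (instructed strategy removal) and the implicit
state decays with a retention factor.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import epochs as _epochs
from ._rng import substream

__all__ = [
    "FEEDBACK_MODES",
    "PhaseSpec",
    "ExperimentDesign",
    "SubjectParams",
    "GroupParams",
    "TrialRecord",
    "SimulatedExperiment",
    "make_design",
    "simulate_subject",
    "simulate_experiment",
    "default_group_params",
    "implicit_asymptote",
    "learning_rate_for_asymptote",
    "min_jerk_position",
    "min_jerk_speed",
]

FEEDBACK_MODES = ("veridical", "rotated", "none")

#: default feedback mode per phase
_PHASE_FEEDBACK = {
    "baseline": "veridical",
    "rotation": "rotated",
    "aftereffect": "none",
    "washout": "veridical",
}

_DEFAULT_PHASE_COUNTS = {"baseline": 80, "rotation": 240, "aftereffect": 40, "washout": 40}


@dataclass(frozen=True)
class PhaseSpec:
    name: str
    n_trials: int
    feedback_mode: str

    def __post_init__(self):
        if self.name not in _epochs.PHASES:
            raise ValueError(f"invalid phase name: {self.name!r}")
        if self.n_trials <= 0:
            raise ValueError(f"phase {self.name}: n_trials must be positive")
        if self.feedback_mode not in FEEDBACK_MODES:
            raise ValueError(f"invalid feedback mode: {self.feedback_mode!r}")


@dataclass
class ExperimentDesign:
    """Trial schedule of one experiment, including the target sequence.

    Targets are presented in pseudorandom cycles: every target appears once
    per cycle (in a fresh random order) before any target repeats.
    """

    phase_schedule: tuple[PhaseSpec, ...]
    rotation_deg: float = 30.0
    n_targets: int = 8
    target_angles: tuple[float, ...] = ()
    target_distance_cm: float = 8.0
    feedback_duration_ms: float = 1200.0
    movement_time_limit_ms: float = 500.0
    target_sequence: np.ndarray = field(default_factory=lambda: np.empty(0))
    seed: int = 0

    @property
    def n_trials(self) -> int:
        return sum(p.n_trials for p in self.phase_schedule)

    @property
    def phase_counts(self) -> dict[str, int]:
        return {p.name: p.n_trials for p in self.phase_schedule}

    def phase_of_trial(self) -> np.ndarray:
        """Phase name per trial index (0-based within the experiment)."""
        return np.repeat([p.name for p in self.phase_schedule],
                         [p.n_trials for p in self.phase_schedule])

    def feedback_of_trial(self) -> np.ndarray:
        return np.repeat([p.feedback_mode for p in self.phase_schedule],
                         [p.n_trials for p in self.phase_schedule])

    def epoch_of_trial(self) -> np.ndarray:
        labels: list[str] = []
        for p in self.phase_schedule:
            labels.extend(_epochs.epoch_labels_for_phase(p.name, p.n_trials))
        return np.asarray(labels, dtype=object)


def make_design(config: dict | None = None, *, seed: int = 0) -> ExperimentDesign:
    """Build the default four-phase design (80/240/40/40 trials) or a variant.

    ``config`` may override ``phase_counts`` (mapping phase name to count),
    ``rotation_deg``, ``n_targets``, ``target_distance_cm``,
    ``feedback_duration_ms`` and ``movement_time_limit_ms``.  The per-trial
    target sequence is pseudorandom in whole cycles generated from ``seed``;
    a trailing partial cycle (when the total is not divisible by the number
    of targets) is a truncated random permutation.
    """
    config = dict(config or {})
    counts = dict(_DEFAULT_PHASE_COUNTS)
    counts.update(config.pop("phase_counts", {}))
    unknown = set(counts) - set(_epochs.PHASES)
    if unknown:
        raise ValueError(f"invalid phase name(s): {sorted(unknown)}")
    for name, n in counts.items():
        if int(n) <= 0:
            raise ValueError(f"phase {name}: trial count must be positive, got {n}")

    schedule = tuple(
        PhaseSpec(name, int(counts[name]), _PHASE_FEEDBACK[name]) for name in _epochs.PHASES
    )
    n_targets = int(config.pop("n_targets", 8))
    if n_targets < 1:
        raise ValueError("n_targets must be >= 1")
    # equally spaced around the circle (8 targets -> 45 deg apart)
    angles = tuple(float(a) for a in np.arange(n_targets) * 360.0 / n_targets)

    design = ExperimentDesign(
        phase_schedule=schedule,
        rotation_deg=float(config.pop("rotation_deg", 30.0)),
        n_targets=n_targets,
        target_angles=angles,
        target_distance_cm=float(config.pop("target_distance_cm", 8.0)),
        feedback_duration_ms=float(config.pop("feedback_duration_ms", 1200.0)),
        movement_time_limit_ms=float(config.pop("movement_time_limit_ms", 500.0)),
        seed=int(seed),
    )
    if config:
        raise ValueError(f"unknown design config keys: {sorted(config)}")

    rng = substream(seed, "design")
    total = design.n_trials
    n_cycles = math.ceil(total / n_targets)
    seq = np.concatenate([rng.permutation(angles) for _ in range(n_cycles)])[:total]
    design.target_sequence = seq
    return design


# --------------------------------------------------------------------------
# subject / group parameters


@dataclass
class SubjectParams:
    """State-space learner parameters for one simulated subject.

    ``retention_a`` and ``learning_rate_b`` are the single-rate model's
    retention and error-sensitivity; ``explicit_gain`` is the fraction of the
    remaining (planned) error compensated by strategic re-aiming;
    ``baseline_bias_deg`` is a static perceptual offset; ``trial_noise_sd_deg``
    the SD of trial-level motor noise; ``aftereffect_retention`` the per-trial
    retention of the implicit state in the absence of feedback.
    """

    retention_a: float = 0.98
    learning_rate_b: float = 0.025
    explicit_gain: float = 0.65
    baseline_bias_deg: float = -2.0
    trial_noise_sd_deg: float = 5.0
    aftereffect_retention: float = 0.998

    def __post_init__(self):
        for name in ("retention_a", "learning_rate_b", "explicit_gain", "aftereffect_retention"):
            val = getattr(self, name)
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {val}")
        if self.trial_noise_sd_deg < 0:
            raise ValueError("trial_noise_sd_deg must be >= 0")


_PARAM_BOUNDS = {
    "retention_a": (0.0, 1.0),
    "learning_rate_b": (0.0, 1.0),
    "explicit_gain": (0.0, 1.0),
    "baseline_bias_deg": (-math.inf, math.inf),
    "trial_noise_sd_deg": (0.0, math.inf),
    "aftereffect_retention": (0.0, 1.0),
}


@dataclass
class GroupParams:
    """Population distribution of subject parameters for one feedback-duration group.

    ``duration_effect_deg`` shifts the group's implicit asymptote (in degrees);
    the default of 0 encodes the null effect of feedback duration.
    """

    group_label: str
    feedback_duration_ms: float
    means: dict[str, float]
    sds: dict[str, float]
    duration_effect_deg: float = 0.0

    def __post_init__(self):
        defaults = dataclasses.asdict(SubjectParams())
        means = dict(defaults)
        means.update(self.means)
        self.means = means
        sds = {k: 0.0 for k in defaults}
        sds.update(self.sds)
        self.sds = sds
        unknown = set(self.means) | set(self.sds) - set(defaults)
        unknown -= set(defaults)
        if unknown:
            raise ValueError(f"unknown SubjectParams field(s): {sorted(unknown)}")
        for k, v in self.sds.items():
            if v < 0:
                raise ValueError(f"between-subject SD for {k} must be >= 0")

    def draw_subject(self, rng: np.random.Generator, rotation_deg: float = 30.0) -> SubjectParams:
        """Draw one subject's parameters (truncated normal per field)."""
        values = {}
        for name, mean in self.means.items():
            lo, hi = _PARAM_BOUNDS[name]
            sd = self.sds[name]
            val = mean if sd == 0 else float(rng.normal(mean, sd))
            values[name] = min(max(val, lo), hi)
        params = SubjectParams(**values)
        if self.duration_effect_deg != 0.0:
            base = implicit_asymptote(params.retention_a, params.learning_rate_b,
                                      params.explicit_gain, rotation_deg)
            params.learning_rate_b = learning_rate_for_asymptote(
                base + self.duration_effect_deg, params.retention_a,
                params.explicit_gain, rotation_deg)
        return params


def implicit_asymptote(a: float, b: float, g: float, rotation_deg: float = 30.0) -> float:
    """Steady state of the implicit process under constant rotation.

    With update x <- a*x + b*(1-g)*(R - x) the fixed point is
    x* = c*R / (1 - a + c) with c = b*(1-g).
    """
    c = b * (1.0 - g)
    q = 1.0 - a
    if q + c == 0:
        return 0.0
    return c * rotation_deg / (q + c)


def learning_rate_for_asymptote(x_star: float, a: float, g: float,
                                rotation_deg: float = 30.0) -> float:
    """Invert :func:`implicit_asymptote` for the learning rate, clipped to [0, 1]."""
    x_star = min(max(x_star, 0.0), 0.999 * rotation_deg)
    q = 1.0 - a
    denom = (rotation_deg - x_star) * (1.0 - g)
    if denom <= 0:
        return 1.0
    return min(max(q * x_star / denom, 0.0), 1.0)


def default_group_params(duration_effects: dict[str, float] | None = None) -> list[GroupParams]:
    """The default calibration: three feedback-duration groups, null effect.

    Subject-level early-aftereffect means come out approximately
    Normal(7 deg, SD 2 deg); the measured adaptation asymptote (mean of the
    last three 8-trial bins) is approximately 20 deg.
    """
    effects = duration_effects or {}
    sds = {"learning_rate_b": 0.005, "explicit_gain": 0.05,
           "baseline_bias_deg": 1.3, "trial_noise_sd_deg": 0.8}
    out = []
    for label, dur in (("SD", 200.0), ("MD", 600.0), ("LD", 1200.0)):
        out.append(GroupParams(group_label=label, feedback_duration_ms=dur,
                               means={}, sds=dict(sds),
                               duration_effect_deg=float(effects.get(label, 0.0))))
    return out


# --------------------------------------------------------------------------
# trajectories


@dataclass
class TrialRecord:
    """One reach: metadata plus (optionally) the sampled hand path.

    ``trajectory`` has shape (n_samples, 3) with columns (t_ms, x_cm, y_cm),
    strictly increasing timestamps and the first sample at the origin.
    ``hand_direction_deg`` is the realised movement direction relative to the
    target (CCW positive) — what an ideal kinematic analysis would recover.
    """

    subject_id: str
    group_label: str
    phase: str
    trial_index: int
    target_angle_deg: float
    feedback_mode: str
    target_onset_ms: float
    hand_direction_deg: float
    cursor_direction_deg: float = math.nan
    trajectory: np.ndarray | None = None


def min_jerk_position(t: np.ndarray, duration: float, amplitude: float) -> np.ndarray:
    """Distance along the reach at time ``t`` for a minimum-jerk profile."""
    tau = np.clip(np.asarray(t, dtype=float) / duration, 0.0, 1.0)
    return amplitude * (10 * tau**3 - 15 * tau**4 + 6 * tau**5)


def min_jerk_speed(t: np.ndarray, duration: float, amplitude: float) -> np.ndarray:
    """Speed of the minimum-jerk profile: 30*A*tau^2*(1-tau)^2 / T."""
    tau = np.clip(np.asarray(t, dtype=float) / duration, 0.0, 1.0)
    return 30.0 * amplitude * tau**2 * (1 - tau) ** 2 / duration


def _synthesize_trajectory(rng: np.random.Generator, direction_deg: float, *,
                           sample_rate_hz: float, amplitude_cm: float,
                           movement_duration_ms: float, onset_delay_ms: float,
                           invalid_kind: str | None) -> np.ndarray:
    """Minimum-jerk reach along ``direction_deg`` with an origin-hold prefix."""
    dt = 1000.0 / sample_rate_hz
    amp = amplitude_cm
    if invalid_kind == "short_reach":
        amp = 7.0
    t = np.arange(0.0, onset_delay_ms + movement_duration_ms + 2 * dt + 0.5 * dt, dt)
    tm = np.clip(t - onset_delay_ms, 0.0, movement_duration_ms)
    r = min_jerk_position(tm, movement_duration_ms, amp)
    if invalid_kind == "reversal":
        # carve a sharp mid-movement dip in radial distance; its slope exceeds
        # the minimum-jerk radial velocity, so r decreases by >> 0.01 cm
        tau = tm / movement_duration_ms
        bump = 1.2 * np.sin(np.pi * np.clip((tau - 0.48) / 0.08, 0.0, 1.0)) ** 2
        r = np.maximum(r - bump, 0.0)
    theta = math.radians(direction_deg)
    return np.column_stack([t, r * math.cos(theta), r * math.sin(theta)])


def _plan_directions(design: ExperimentDesign, params: SubjectParams) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic part of the movement direction, per trial.

    Returns (planned hand direction rel. to target, implicit state), both
    length ``design.n_trials``.  The planned direction is
    ``baseline_bias + x_t + explicit_t``; trial noise is added by the caller.
    """
    a, b = params.retention_a, params.learning_rate_b
    g = params.explicit_gain
    n = design.n_trials
    feedback = design.feedback_of_trial()
    planned = np.empty(n)
    state = np.empty(n)
    x = 0.0
    for t in range(n):
        mode = feedback[t]
        rot = design.rotation_deg if mode == "rotated" else 0.0
        expl = 0.0 if mode == "none" else g * (rot - x)
        planned[t] = params.baseline_bias_deg + x + expl
        state[t] = x
        if mode == "none":
            x = params.aftereffect_retention * x
        else:
            e = rot - (x + expl)
            x = a * x + b * e
    return planned, state


def simulate_subject(design: ExperimentDesign, params: SubjectParams, seed: int, *,
                     subject_id: str = "s00", group_label: str = "NA",
                     trajectories: bool = True, sample_rate_hz: float = 200.0,
                     movement_duration_ms: tuple[float, float] = (430.0, 40.0),
                     onset_delay_ms: tuple[float, float] = (600.0, 120.0),
                     reach_amplitude_cm: float = 8.4,
                     invalid_rate: float = 0.01) -> list[TrialRecord]:
    """Simulate every trial of one subject.

    The implicit state follows x_{t+1} = a*x_t + b*e_t while feedback is
    present (e_t the planned-movement cursor error) and decays with the
    aftereffect retention factor during the no-feedback phase, where the
    explicit component is forced to zero.  The hand direction is the planned
    direction plus Normal(0, trial_noise_sd) noise; a minimum-jerk trajectory
    of ~430 ms duration and ``reach_amplitude_cm`` amplitude is synthesized
    along it.  A fraction ``invalid_rate`` of trials is corrupted (short
    reach or mid-movement reversal) to exercise exclusion logic.
    """
    rng = substream(seed, "subject")
    n = design.n_trials
    planned, _ = _plan_directions(design, params)
    noise = (rng.normal(0.0, params.trial_noise_sd_deg, size=n)
             if params.trial_noise_sd_deg > 0 else np.zeros(n))
    hand = planned + noise

    phases = design.phase_of_trial()
    feedback = design.feedback_of_trial()
    targets = design.target_sequence

    invalid_kind = np.array([None] * n, dtype=object)
    if invalid_rate > 0:
        bad = rng.random(n) < invalid_rate
        kinds = rng.choice(["short_reach", "reversal"], size=int(bad.sum()))
        invalid_kind[bad] = kinds

    if trajectories:
        durations = np.clip(rng.normal(*movement_duration_ms, size=n), 250.0, 650.0)
        delays = np.clip(rng.normal(*onset_delay_ms, size=n), 200.0, 1500.0)

    records = []
    for t in range(n):
        traj = None
        if trajectories:
            absolute_dir = targets[t] + hand[t]
            traj = _synthesize_trajectory(
                rng, absolute_dir, sample_rate_hz=sample_rate_hz,
                amplitude_cm=reach_amplitude_cm, movement_duration_ms=float(durations[t]),
                onset_delay_ms=float(delays[t]), invalid_kind=invalid_kind[t])
        mode = str(feedback[t])
        if mode == "rotated":
            cursor = hand[t] - design.rotation_deg  # clockwise cursor displacement
        elif mode == "veridical":
            cursor = hand[t]
        else:
            cursor = math.nan  # no feedback shown
        records.append(TrialRecord(
            subject_id=subject_id, group_label=group_label, phase=str(phases[t]),
            trial_index=t, target_angle_deg=float(targets[t]),
            feedback_mode=mode, target_onset_ms=0.0,
            hand_direction_deg=float(hand[t]), cursor_direction_deg=float(cursor),
            trajectory=traj))
    return records


# --------------------------------------------------------------------------
# whole experiments


@dataclass
class SimulatedExperiment:
    """All trial records of a simulated multi-group experiment plus ground truth.

    ``trial_table`` is trial-level (one row per reach, with the commanded
    movement direction); ``ground_truth`` holds the drawn subject parameters
    and the noise-free subject and group epoch means used by recovery tests.
    """

    records: list[TrialRecord]
    trial_table: pd.DataFrame
    ground_truth: dict

    def to_samples_frame(self) -> pd.DataFrame:
        """Long-format sample-level table (one row per trajectory sample)."""
        rows = []
        for r in self.records:
            if r.trajectory is None:
                raise ValueError("experiment was simulated without trajectories")
            m = len(r.trajectory)
            rows.append(pd.DataFrame({
                "subject_id": [r.subject_id] * m, "group": [r.group_label] * m,
                "phase": [r.phase] * m, "trial": [r.trial_index] * m,
                "target_deg": [r.target_angle_deg] * m,
                "t_ms": r.trajectory[:, 0], "x_cm": r.trajectory[:, 1],
                "y_cm": r.trajectory[:, 2]}))
        return pd.concat(rows, ignore_index=True)

    def write_csv(self, trials_path, samples_path=None, ground_truth_path=None) -> None:
        self.trial_table.to_csv(trials_path, index=False)
        if samples_path is not None:
            self.to_samples_frame().to_csv(samples_path, index=False)
        if ground_truth_path is not None:
            with open(ground_truth_path, "w") as fh:
                json.dump(self.ground_truth, fh, indent=1, default=float)


def _subject_truth(design: ExperimentDesign, params: SubjectParams) -> dict[str, float]:
    """Noise-free epoch means for one subject (the generator's ground truth)."""
    planned, _ = _plan_directions(design, params)
    labels = design.epoch_of_trial()
    df = pd.DataFrame({"epoch": labels, "y": planned})
    return df.groupby("epoch", sort=False)["y"].mean().to_dict()


def simulate_experiment(design: ExperimentDesign, group_params: Sequence[GroupParams],
                        n_per_group: int, seed: int, *, trajectories: bool = True,
                        invalid_rate: float = 0.01) -> SimulatedExperiment:
    """Simulate ``n_per_group`` subjects in each group; reproducible under ``seed``.

    Returns all trial records, a trial-level table and a ground-truth record
    with each subject's drawn parameters and each subject's / group's true
    (noise-free) epoch means.
    """
    if not group_params:
        raise ValueError("group_params must contain at least one group")
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")

    records: list[TrialRecord] = []
    subj_params: dict[str, dict] = {}
    subj_truth: dict[str, dict[str, float]] = {}
    group_truth: dict[str, dict[str, float]] = {}
    rng_groups = substream(seed, "experiment")
    subject_seeds = rng_groups.integers(0, 2**31 - 1, size=len(group_params) * n_per_group)

    idx = 0
    for gp in group_params:
        truths = []
        for k in range(n_per_group):
            sid = f"{gp.group_label}_{k:03d}"
            draw_rng = substream(seed, "subject-params", index=idx)
            params = gp.draw_subject(draw_rng, rotation_deg=design.rotation_deg)
            records.extend(simulate_subject(
                design, params, int(subject_seeds[idx]), subject_id=sid,
                group_label=gp.group_label, trajectories=trajectories,
                invalid_rate=invalid_rate))
            subj_params[sid] = dataclasses.asdict(params)
            truth = _subject_truth(design, params)
            subj_truth[sid] = truth
            truths.append(truth)
            idx += 1
        keys = truths[0].keys()
        group_truth[gp.group_label] = {k: float(np.mean([t[k] for t in truths])) for k in keys}

    trial_table = pd.DataFrame({
        "subject_id": [r.subject_id for r in records],
        "group": [r.group_label for r in records],
        "phase": [r.phase for r in records],
        "trial": [r.trial_index for r in records],
        "target_deg": [r.target_angle_deg for r in records],
        "feedback_mode": [r.feedback_mode for r in records],
        "movement_direction_deg": [r.hand_direction_deg for r in records],
        "cursor_direction_deg": [r.cursor_direction_deg for r in records],
    })
    # population-level truth: epoch means at the population-mean parameters
    pop_truth = {}
    for gp in group_params:
        mean_params = SubjectParams(**gp.means)
        if gp.duration_effect_deg != 0.0:
            base = implicit_asymptote(mean_params.retention_a, mean_params.learning_rate_b,
                                      mean_params.explicit_gain, design.rotation_deg)
            mean_params.learning_rate_b = learning_rate_for_asymptote(
                base + gp.duration_effect_deg, mean_params.retention_a,
                mean_params.explicit_gain, design.rotation_deg)
        pop_truth[gp.group_label] = _subject_truth(design, mean_params)

    ground_truth = {
        "seed": int(seed),
        "subject_params": subj_params,
        "subject_epoch_means": subj_truth,
        "group_epoch_means": group_truth,
        "population_epoch_means": pop_truth,
        "duration_effect_deg": {gp.group_label: gp.duration_effect_deg for gp in group_params},
    }
    return SimulatedExperiment(records=records, trial_table=trial_table,
                               ground_truth=ground_truth)
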