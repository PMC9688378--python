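"""Bimanual tracking task (BTT) simulation.

The task: two dials, one per hand, steer a cursor (left hand -> ordinate,
right hand -> abscissa) to follow a dot moving at constant speed along an
inclined line.  Conditions are defined by the required inter-hand speed
ratio: 1:1 (iso-frequency), 1:3 (right hand three times faster) and 3:1
(left hand three times faster).  A session is 4 blocks x 3 conditions x 13
trials = 156 trials, pseudo-randomized so that every condition precedes
every other condition about equally often.

Units are normalized: the target line has length 1 and the dot traverses it
during the execution stage, so tracking errors are scale-free and
comparable across conditions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np

__all__ = [
    "Group",
    "Condition",
    "TrialTimeline",
    "SessionSchedule",
    "ParticipantProfile",
    "TargetTrajectory",
    "DialTrace",
    "make_schedule",
    "target_trajectory",
    "simulate_trial",
    "dials_to_cursor",
    "simulate_session",
]

DIAL_FS = 100.0  # shaft-encoder sampling rate, Hz


class Group(str, Enum):
    YOUNGER = "younger"
    OLDER = "older"


class Condition(Enum):
    """Inter-hand frequency-ratio condition (left_factor, right_factor)."""

    ONE_ONE = (1, 1)
    ONE_THREE = (1, 3)
    THREE_ONE = (3, 1)

    @property
    def left_factor(self) -> int:
        return self.value[0]

    @property
    def right_factor(self) -> int:
        return self.value[1]

    @property
    def line_angle(self) -> float:
        """Angle of the target line from the abscissa (radians).

        Left-dial rotation maps to y, right-dial rotation to x, so a
        condition requiring the left hand to turn ``l`` units per ``r``
        right-hand units produces a line at atan(l / r).
        """
        return math.atan2(self.left_factor, self.right_factor)

    @property
    def label(self) -> str:
        return {"ONE_ONE": "1:1", "ONE_THREE": "1:3", "THREE_ONE": "3:1"}[self.name]

    @classmethod
    def from_label(cls, label: str) -> "Condition":
        for c in cls:
            if c.label == label or c.name == label:
                return c
        raise ValueError(f"unknown condition label {label!r}")


@dataclass(frozen=True)
class TrialTimeline:
    """Trial stage structure and the analysis windows on the epoch axis.

    t = 0 is execution-stage onset.  The 1 s rest and 2 s planning stages
    precede it; execution lasts 5 s but EEG epochs end at +3.5 s and the
    execution analysis window skips the first second (movement-initiation
    artefacts in the real recordings).
    """

    rest_s: float = 1.0
    plan_s: float = 2.0
    exec_s: float = 5.0
    epoch_start_s: float = -3.0
    epoch_end_s: float = 3.5
    plan_window: tuple[float, float] = (-2.0, 0.0)
    exec_window: tuple[float, float] = (1.0, 3.0)
    rest_window: tuple[float, float] = (-3.0, -2.0)
    baseline_window: tuple[float, float] = (-2.5, -2.2)

    def __post_init__(self) -> None:
        if self.exec_s <= 0 or self.plan_s <= 0 or self.rest_s <= 0:
            raise ValueError("stage durations must be positive")
        for name in ("plan_window", "exec_window", "rest_window", "baseline_window"):
            lo, hi = getattr(self, name)
            if not (self.epoch_start_s <= lo < hi <= self.epoch_end_s):
                raise ValueError(f"{name} {lo, hi} not within the epoch")

    @property
    def trial_s(self) -> float:
        return self.rest_s + self.plan_s + self.exec_s


@dataclass
class SessionSchedule:
    """Ordered trial list for one session."""

    n_blocks: int
    trials_per_condition: int
    trials: list[tuple[int, int, Condition]]  # (block, trial index, condition)
    seed: int

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def trials_per_block(self) -> int:
        return self.trials_per_condition * len(Condition)

    def block_duration_s(self, timeline: TrialTimeline | None = None) -> float:
        timeline = timeline or TrialTimeline()
        return self.trials_per_block * timeline.trial_s

    def session_duration_s(self, timeline: TrialTimeline | None = None) -> float:
        timeline = timeline or TrialTimeline()
        return self.n_trials * timeline.trial_s

    def transition_counts(self) -> dict[tuple[Condition, Condition], int]:
        """Counts of consecutive condition pairs, within blocks."""
        counts: dict[tuple[Condition, Condition], int] = {
            (a, b): 0 for a in Condition for b in Condition
        }
        for (b0, _, c0), (b1, _, c1) in zip(self.trials, self.trials[1:]):
            if b0 == b1:
                counts[(c0, c1)] += 1
        return counts


@dataclass(frozen=True)
class ParticipantProfile:
    """Generator parameters standing in for unobserved participant behavior.

    motor_noise_sd : SD of the Gaussian angular-velocity noise added to each
        hand's per-sample displacement (normalized units per sample).
    lag_s : tracking delay; the controller follows the target velocity
        ``lag_s`` seconds late.
    coupling : 0-1, tendency of the slow hand's speed to drift toward the
        fast hand's speed (spatiotemporal coupling of the limbs); only
        non-iso-frequency conditions are affected.
    """

    group: Group
    motor_noise_sd: float = 0.0
    lag_s: float = 0.0
    coupling: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.motor_noise_sd < 0:
            raise ValueError("motor_noise_sd must be >= 0")
        if not 0.0 <= self.coupling <= 1.0:
            raise ValueError("coupling must be in [0, 1]")
        if self.lag_s < 0:
            raise ValueError("lag_s must be >= 0")


@dataclass
class TargetTrajectory:
    """Constant-speed dot on the condition's inclined line (length 1)."""

    positions: np.ndarray  # (n, 2)
    fs: float
    condition: Condition
    origin: np.ndarray = field(default_factory=lambda: np.zeros(2))

    @property
    def direction(self) -> np.ndarray:
        a = self.condition.line_angle
        return np.array([math.cos(a), math.sin(a)])


@dataclass
class DialTrace:
    """Cumulative angular displacement of both dials, normalized units."""

    left_angle: np.ndarray
    right_angle: np.ndarray
    fs: float
    condition: Condition

    def __post_init__(self) -> None:
        if len(self.left_angle) != len(self.right_angle):
            raise ValueError("left and right series must have equal length")


def make_schedule(
    n_blocks: int = 4,
    trials_per_condition: int = 13,
    seed: int = 0,
    max_attempts: int = 500,
) -> SessionSchedule:
    """Pseudo-randomized session schedule with balanced condition transitions.

    Within-block consecutive-pair counts are constrained so that, summed over
    the session, the ordered transition counts a->b and b->a differ by at
    most 1 for every pair of distinct conditions ("all conditions precede
    one another to an equal extent").  A greedy constrained shuffle is used;
    construction restarts on dead ends and is deterministic given ``seed``.
    """
    if n_blocks < 1 or trials_per_condition < 1:
        raise ValueError("n_blocks and trials_per_condition must be >= 1")
    rng = np.random.default_rng(seed)
    conds = list(Condition)

    for _ in range(max_attempts):
        counts = {(a, b): 0 for a in conds for b in conds}
        trials: list[tuple[int, int, Condition]] = []
        ok = True
        for block in range(n_blocks):
            remaining = {c: trials_per_condition for c in conds}
            prev: Condition | None = None
            for idx in range(trials_per_condition * len(conds)):
                cands = [c for c in conds if remaining[c] > 0]
                if prev is not None:
                    cands = [
                        c
                        for c in cands
                        if c is prev
                        or abs(counts[(prev, c)] + 1 - counts[(c, prev)]) <= 1
                    ]
                if not cands:
                    ok = False
                    break
                weights = np.array([remaining[c] for c in cands], dtype=float)
                choice = cands[rng.choice(len(cands), p=weights / weights.sum())]
                trials.append((block, idx, choice))
                if prev is not None:
                    counts[(prev, choice)] += 1
                remaining[choice] -= 1
                prev = choice
            if not ok:
                break
        if ok and all(
            abs(counts[(a, b)] - counts[(b, a)]) <= 1
            for a in conds
            for b in conds
            if a is not b
        ):
            return SessionSchedule(n_blocks, trials_per_condition, trials, seed)
    raise RuntimeError("could not build a transition-balanced schedule")


def target_trajectory(
    condition: Condition,
    timeline: TrialTimeline | None = None,
    fs: float = DIAL_FS,
) -> TargetTrajectory:
    """Constant-speed target positions during the execution stage.

    The dot starts at the line origin and reaches the endpoint (unit
    distance along the condition's line angle) after ``exec_s`` seconds;
    position k is sampled at the end of the k-th sample interval.
    """
    timeline = timeline or TrialTimeline()
    if timeline.exec_s <= 0:
        raise ValueError("exec_s must be positive")
    if fs <= 0:
        raise ValueError("fs must be positive")
    n = int(round(timeline.exec_s * fs))
    progress = (np.arange(n) + 1) / n  # fraction of line traversed
    a = condition.line_angle
    positions = np.column_stack(
        [progress * math.cos(a), progress * math.sin(a)]
    )
    return TargetTrajectory(positions=positions, fs=fs, condition=condition)


def simulate_trial(
    condition: Condition,
    profile: ParticipantProfile,
    timeline: TrialTimeline | None = None,
    seed: int | np.random.Generator = 0,
    fs: float = DIAL_FS,
) -> DialTrace:
    """Simulate one trial's dial rotations during the execution stage.

    The controller tracks the target velocity delayed by ``lag_s``; Gaussian
    angular-velocity noise (independent per hand) and a coupling term
    pulling the slow hand's speed toward the fast hand's are added.  With a
    noise-free, lag-free, uncoupled profile the cursor reproduces the target
    exactly.
    """
    timeline = timeline or TrialTimeline()
    target = target_trajectory(condition, timeline, fs)
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    n = len(target.positions)
    # ideal per-sample increments along each axis (x = right, y = left)
    a = condition.line_angle
    inc_x = np.full(n, math.cos(a) / n)
    inc_y = np.full(n, math.sin(a) / n)
    lag_samples = int(round(profile.lag_s * fs))
    if lag_samples > 0:
        inc_x = np.concatenate([np.zeros(lag_samples), inc_x[: n - lag_samples]])
        inc_y = np.concatenate([np.zeros(lag_samples), inc_y[: n - lag_samples]])
    # coupling: slow hand's speed drifts toward the fast hand's speed
    c = profile.coupling
    if c > 0 and condition is not Condition.ONE_ONE:
        if condition.left_factor > condition.right_factor:  # left fast, right slow
            inc_x = inc_x + c * (inc_y - inc_x)
        else:
            inc_y = inc_y + c * (inc_x - inc_y)
    if profile.motor_noise_sd > 0:
        inc_x = inc_x + rng.normal(0.0, profile.motor_noise_sd, n)
        inc_y = inc_y + rng.normal(0.0, profile.motor_noise_sd, n)
    return DialTrace(
        left_angle=np.cumsum(inc_y),
        right_angle=np.cumsum(inc_x),
        fs=fs,
        condition=condition,
    )


def dials_to_cursor(trace: DialTrace) -> np.ndarray:
    """Cursor path: right dial drives the abscissa, left dial the ordinate."""
    return np.column_stack([trace.right_angle, trace.left_angle])


def simulate_session(
    profile: ParticipantProfile,
    schedule: SessionSchedule,
    timeline: TrialTimeline | None = None,
    seed: int | None = None,
    fs: float = DIAL_FS,
) -> list[tuple[int, int, Condition, DialTrace]]:
    """Simulate every trial of a session; returns (block, idx, condition, trace)."""
    timeline = timeline or TrialTimeline()
    rng = np.random.default_rng(profile.seed if seed is None else seed)
    return [
        (block, idx, cond, simulate_trial(cond, profile, timeline, rng, fs))
        for block, idx, cond in schedule.trials
    ]
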