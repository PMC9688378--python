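"""Tracking-error score and per-trial behavior tables.

The per-trial performance score is the time-average, over the execution
stage, of the Euclidean distance between the cursor and the target dot plus
the orthogonal distance from the cursor to the (infinite) target line.
Lower is better; a perfect trial scores 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .task import (
    Condition,
    DialTrace,
    Group,
    ParticipantProfile,
    SessionSchedule,
    TargetTrajectory,
    TrialTimeline,
    dials_to_cursor,
    simulate_session,
    target_trajectory,
)

__all__ = ["TrackingScore", "tracking_error", "score_session", "behavior_table"]

BEHAVIOR_COLUMNS = [
    "participant",
    "group",
    "block",
    "trial",
    "condition",
    "tracking_error",
]


@dataclass(frozen=True)
class TrackingScore:
    value: float
    euclidean_term: float
    orthogonal_term: float
    condition: Condition


def tracking_error(
    cursor: np.ndarray, target: TargetTrajectory
) -> TrackingScore:
    """Mean of (cursor-to-dot distance + cursor-to-line orthogonal distance).

    The orthogonal term uses the infinite line through the target segment;
    both terms are averaged over all execution-stage samples.

    Parameters
    ----------
    cursor : (n, 2) cursor positions on the same time base as ``target``.
    """
    cursor = np.asarray(cursor, dtype=float)
    if cursor.ndim != 2 or cursor.shape[1] != 2:
        raise ValueError("cursor must be an (n, 2) array")
    if cursor.shape[0] == 0:
        raise ValueError("empty cursor input")
    if cursor.shape[0] != target.positions.shape[0]:
        raise ValueError(
            f"cursor ({cursor.shape[0]}) and target "
            f"({target.positions.shape[0]}) lengths differ"
        )
    diff = cursor - target.positions
    euclid = np.hypot(diff[:, 0], diff[:, 1])
    u = target.direction
    rel = cursor - target.origin
    ortho = np.abs(rel[:, 0] * u[1] - rel[:, 1] * u[0])  # |cross(rel, u)|
    return TrackingScore(
        value=float(np.mean(euclid + ortho)),
        euclidean_term=float(np.mean(euclid)),
        orthogonal_term=float(np.mean(ortho)),
        condition=target.condition,
    )


def score_session(
    participant: str,
    group: Group,
    session: list[tuple[int, int, Condition, DialTrace]],
    timeline: TrialTimeline | None = None,
) -> pd.DataFrame:
    """One scored row per trial of a simulated session."""
    timeline = timeline or TrialTimeline()
    rows = []
    targets: dict[Condition, TargetTrajectory] = {}
    for block, idx, cond, trace in session:
        if cond not in targets:
            targets[cond] = target_trajectory(cond, timeline, trace.fs)
        score = tracking_error(dials_to_cursor(trace), targets[cond])
        rows.append(
            {
                "participant": participant,
                "group": group.value,
                "block": block,
                "trial": idx,
                "condition": cond.label,
                "tracking_error": score.value,
            }
        )
    return pd.DataFrame(rows, columns=BEHAVIOR_COLUMNS)


def behavior_table(
    profiles: dict[str, ParticipantProfile],
    schedule: SessionSchedule,
    timeline: TrialTimeline | None = None,
) -> pd.DataFrame:
    """Simulate and score full sessions for a set of participants.

    Returns one row per participant x trial with a stable column order.
    Raises if any participant's session is incomplete.
    """
    timeline = timeline or TrialTimeline()
    frames = []
    for pid, profile in profiles.items():
        session = simulate_session(profile, schedule, timeline)
        if len(session) != schedule.n_trials:
            raise RuntimeError(
                f"incomplete session for {pid}: "
                f"{len(session)}/{schedule.n_trials} trials"
            )
        frames.append(score_session(pid, profile.group, session, timeline))
    if not frames:
        return pd.DataFrame(columns=BEHAVIOR_COLUMNS)
    return pd.concat(frames, ignore_index=True)
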