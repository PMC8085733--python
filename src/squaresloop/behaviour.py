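"""Movement metrics, turn detection and policy classification.

Directions are discretised to the 8 compass sectors (45 deg spacing).  A turn
is a change of discretised direction preceded by at least three frames of one
direction and sustained for at least three frames; stationary frames do not
break a direction run.  Turns are grouped into six policy types; runs of
same-rotation small turns collapse into a single Circle and two-step
cardinal-diagonal-cardinal corners into a single Perpendicular-Cardinal.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

MOVING_EPS = 0.1  # px/frame below which the mouse counts as stopped

DIRECTION_NAMES = ("R", "DR", "D", "DL", "L", "UL", "U", "UR")  # index k = 45k deg

POLICIES = (
    "Horizontal",
    "Vertical",
    "PerpendicularCardinal",
    "NonCardinal",
    "HesitantStraight",
    "Circle",
)

# collapse windows (frames)
CIRCLE_WINDOW = 30
CORNER_WINDOW = 15

__all__ = [
    "TurnEvent",
    "TrialBehaviour",
    "compute_kinematics",
    "time_spent_moving",
    "discretise_directions",
    "detect_turns",
    "detect_hesitations",
    "classify_turn_policy",
    "classify_trial_turns",
    "analyse_trial",
    "dominant_policy_stats",
    "motor_control_index",
    "POLICIES",
    "DIRECTION_NAMES",
    "MOVING_EPS",
]


@dataclass(frozen=True)
class TurnEvent:
    frame: int  # onset frame (first frame of the new direction / of resumption)
    dir_from: int  # 0-7, or -1 for a pure hesitation's pre-stop direction copy
    dir_to: int
    policy: str
    merged_span: tuple[int, int] | None = None  # (first, last) onset for collapses


@dataclass
class TrialBehaviour:
    time_moving_s: float
    time_to_movement_onset_s: float
    mean_speed_px_per_frame: float
    mean_accel: float
    mean_jerk: float
    n_turns: int
    policy_counts: dict[str, int]
    turns: list[TurnEvent]

    def count(self, policy: str) -> int:
        return self.policy_counts.get(policy, 0)


def compute_kinematics(mouse_trace: np.ndarray, eps: float = MOVING_EPS):
    """Per-frame speed, acceleration and jerk plus their means.

    speed_t = ||(dx, dy)_t||; accel and jerk are successive first differences.
    Means are restricted to spans where all underlying frames are moving;
    undefined means are reported as NaN.
    """
    mouse_trace = np.asarray(mouse_trace, float)
    if mouse_trace.shape[0] < 4:
        raise ValueError("need at least 4 frames for jerk")
    speed = np.hypot(mouse_trace[:, 0], mouse_trace[:, 1])
    accel = np.diff(speed)
    jerk = np.diff(accel)
    moving = speed > eps
    m_a = moving[1:] & moving[:-1]
    m_j = m_a[1:] & m_a[:-1]
    mean_speed = float(speed[moving].mean()) if moving.any() else 0.0
    mean_accel = float(accel[m_a].mean()) if m_a.any() else float("nan")
    mean_jerk = float(jerk[m_j].mean()) if m_j.any() else float("nan")
    return speed, accel, jerk, mean_speed, mean_accel, mean_jerk


def time_spent_moving(
    mouse_trace: np.ndarray, eps: float = MOVING_EPS, fps: float = 60.0
) -> tuple[float, float]:
    """Seconds with speed above ``eps`` and the movement-onset time (NaN if
    the mouse never moves)."""
    mouse_trace = np.asarray(mouse_trace, float)
    speed = np.hypot(mouse_trace[:, 0], mouse_trace[:, 1])
    moving = speed > eps
    t_moving = float(moving.sum()) / fps
    onset = float(np.argmax(moving)) / fps if moving.any() else float("nan")
    return t_moving, onset


def discretise_directions(
    mouse_trace: np.ndarray, eps: float = MOVING_EPS
) -> tuple[np.ndarray, np.ndarray]:
    """Direction index (0-7, 45 deg sectors) for every moving frame.

    Returns ``(dirs, frames)`` where ``frames`` are the original frame indices
    of the moving frames.  A boundary angle (exactly between two sectors) is
    assigned to the clockwise-next sector (the larger angle, y-down).
    """
    mouse_trace = np.asarray(mouse_trace, float)
    speed = np.hypot(mouse_trace[:, 0], mouse_trace[:, 1])
    frames = np.flatnonzero(speed > eps)
    ang = np.degrees(np.arctan2(mouse_trace[frames, 1], mouse_trace[frames, 0]))
    dirs = np.floor((ang % 360.0 + 22.5) / 45.0).astype(int) % 8
    return dirs, frames


def detect_turns(
    dirs: np.ndarray, frames: np.ndarray | None = None
) -> list[tuple[int, int, int]]:
    """Turns in a discretised direction sequence.

    A turn is emitted at each direction change whose previous run and next run
    both span >= 3 entries.  Returns ``(onset, dir_from, dir_to)`` tuples,
    with onsets mapped through ``frames`` when given.
    """
    dirs = np.asarray(dirs, int)
    if frames is None:
        frames = np.arange(len(dirs))
    if len(dirs) == 0:
        return []
    change = np.flatnonzero(np.diff(dirs) != 0) + 1
    starts = np.concatenate([[0], change])
    lengths = np.diff(np.concatenate([starts, [len(dirs)]]))
    turns = []
    for i in range(1, len(starts)):
        if lengths[i - 1] >= 3 and lengths[i] >= 3:
            onset = starts[i]
            turns.append((int(frames[onset]), int(dirs[onset - 1]), int(dirs[onset])))
    return turns


def detect_hesitations(
    mouse_trace: np.ndarray, eps: float = MOVING_EPS, min_stop: int = 3
) -> list[tuple[int, int]]:
    """Full stops of >= ``min_stop`` frames after which the same discretised
    direction resumes.  Returns ``(resume_frame, direction)`` pairs."""
    dirs, frames = discretise_directions(np.asarray(mouse_trace, float), eps)
    events = []
    for i in range(1, len(frames)):
        gap = frames[i] - frames[i - 1] - 1
        if gap >= min_stop and dirs[i] == dirs[i - 1]:
            events.append((int(frames[i]), int(dirs[i])))
    return events


def _signed_steps(d_from: int, d_to: int) -> int:
    """Direction change in 45 deg steps, in [-4, 3] (-4 = half turn)."""
    return (d_to - d_from + 4) % 8 - 4


def classify_turn_policy(d_from: int, d_to: int) -> str:
    """Policy label for a single non-collapsed turn."""
    if {d_from, d_to} == {0, 4}:
        return "Horizontal"
    if {d_from, d_to} == {2, 6}:
        return "Vertical"
    if d_from % 2 == 0 and d_to % 2 == 0 and abs(_signed_steps(d_from, d_to)) == 2:
        return "PerpendicularCardinal"
    return "NonCardinal"


def classify_trial_turns(
    raw_turns: list[tuple[int, int, int]],
    hesitations: list[tuple[int, int]] | None = None,
) -> list[TurnEvent]:
    """Label raw turns, collapsing circles and rounded corners, and merge in
    hesitation events.  Collapsing is resolved left-to-right: circle runs
    first (>= 3 same-rotation small turns within CIRCLE_WINDOW frames), then
    corner pairs (cardinal-diagonal-cardinal 90 deg within CORNER_WINDOW)."""
    events: list[TurnEvent] = []
    n = len(raw_turns)
    i = 0
    while i < n:
        f_i, a_i, b_i = raw_turns[i]
        step_i = _signed_steps(a_i, b_i)
        # try circle: extend run of same-sign small turns within the window
        j = i
        if abs(step_i) in (1, 2):
            sign = np.sign(step_i)
            while j + 1 < n:
                f_j, a_j, b_j = raw_turns[j + 1]
                s = _signed_steps(a_j, b_j)
                if (
                    abs(s) in (1, 2)
                    and np.sign(s) == sign
                    and f_j - f_i <= CIRCLE_WINDOW
                ):
                    j += 1
                else:
                    break
        if j - i + 1 >= 3:
            events.append(
                TurnEvent(f_i, a_i, raw_turns[j][2], "Circle", (f_i, raw_turns[j][0]))
            )
            i = j + 1
            continue
        # try rounded corner: 45 deg onto a diagonal then 45 deg back to cardinal
        if (
            i + 1 < n
            and abs(step_i) == 1
            and a_i % 2 == 0
            and b_i % 2 == 1
        ):
            f_k, a_k, b_k = raw_turns[i + 1]
            s_k = _signed_steps(a_k, b_k)
            if (
                a_k == b_i
                and b_k % 2 == 0
                and s_k == step_i
                and f_k - f_i <= CORNER_WINDOW
            ):
                events.append(
                    TurnEvent(f_i, a_i, b_k, "PerpendicularCardinal", (f_i, f_k))
                )
                i += 2
                continue
        events.append(TurnEvent(f_i, a_i, b_i, classify_turn_policy(a_i, b_i)))
        i += 1
    for frame, d in hesitations or []:
        events.append(TurnEvent(frame, d, d, "HesitantStraight"))
    events.sort(key=lambda e: e.frame)
    return events


def analyse_trial(
    mouse_trace: np.ndarray, eps: float = MOVING_EPS, fps: float = 60.0
) -> TrialBehaviour:
    """All per-trial behavioural measures from a mouse displacement trace."""
    mouse_trace = np.asarray(mouse_trace, float)
    _, _, _, mean_speed, mean_accel, mean_jerk = compute_kinematics(mouse_trace, eps)
    t_moving, onset = time_spent_moving(mouse_trace, eps, fps)
    dirs, frames = discretise_directions(mouse_trace, eps)
    turns = detect_turns(dirs, frames)
    hes = detect_hesitations(mouse_trace, eps)
    events = classify_trial_turns(turns, hes)
    counts = Counter(e.policy for e in events)
    return TrialBehaviour(
        time_moving_s=t_moving,
        time_to_movement_onset_s=onset,
        mean_speed_px_per_frame=mean_speed,
        mean_accel=mean_accel,
        mean_jerk=mean_jerk,
        n_turns=len(events),
        policy_counts={p: counts.get(p, 0) for p in POLICIES},
        turns=events,
    )


def dominant_policy_stats(
    trial_events: list[list[TurnEvent]],
) -> tuple[str, list[int], list[int]]:
    """Dominant policy across a session and per-trial counts.

    The dominant policy is the one with the highest share of turns over all
    trials; ties go to the policy occurring earliest in the session.  Returns
    ``(dominant, per-trial dominant-policy counts, per-trial total turns)``.
    """
    all_events = [e for trial in trial_events for e in trial]
    if not all_events:
        raise ValueError("no turns in session: dominant policy undefined")
    counts = Counter(e.policy for e in all_events)
    first_seen: dict[str, int] = {}
    for k, e in enumerate(all_events):
        first_seen.setdefault(e.policy, k)
    best = max(counts, key=lambda p: (counts[p], -first_seen[p]))
    dom_counts = [sum(e.policy == best for e in trial) for trial in trial_events]
    totals = [len(trial) for trial in trial_events]
    return best, dom_counts, totals


def motor_control_index(areas: np.ndarray, reaction_times: np.ndarray) -> float:
    """Mean area traversed outside the path times mean reaction time (lower is
    better)."""
    areas = np.asarray(areas, float)
    reaction_times = np.asarray(reaction_times, float)
    if areas.size == 0 or reaction_times.size == 0:
        raise ValueError("need at least one path trial")
    return float(areas.mean() * reaction_times.mean())
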