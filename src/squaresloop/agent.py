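"""Synthetic participants: seeded mouse traces built from the six turn
policies, a gaze agent that abandons its hypothesis when accumulated
prediction error crosses a threshold, eye-tracker artifact injection, and
end-of-trial agency judgements.

The agents are sign-level stand-ins for human participants: they reproduce
the directions of the task's behavioural effects (harder discrimination
under wide jitter, prediction-error peaks at hypothesis switches), not their
magnitudes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .behaviour import classify_turn_policy
from .preprocess import EyeTrace
from .task import TaskConfig, TrialLog
from .gaze import per_square_prediction_error

ACCUMULATOR_DECAY = 0.9  # leaky sum of one-step PE per frame
SWITCH_REFRACTORY_FRAMES = 12  # ~200 ms at 60 Hz
RECENT_PE_FRAMES = 12  # lookback for choosing the next hypothesis

AQ_MEAN, AQ_SD = 21.43, 5.89  # sample moments used for the synthetic covariate

_CARDINALS = (0, 2, 4, 6)
_DIAGONALS = (1, 3, 5, 7)

__all__ = [
    "AgentProfile",
    "MouseTraceTruth",
    "GazeAgentResult",
    "generate_mouse_trace",
    "simulate_gaze_agent",
    "inject_eye_noise",
    "judge_agency",
    "sample_aq",
]


@dataclass(frozen=True)
class AgentProfile:
    """Tunable parameters of one synthetic participant."""

    policy_weights: tuple[float, ...] = (0.15, 0.10, 0.15, 0.30, 0.20, 0.10)
    # order: Horizontal, Vertical, PerpendicularCardinal, NonCardinal,
    #        HesitantStraight, Circle
    base_speed_px_per_frame: float = 6.0
    pause_prob: float = 0.08
    switch_threshold_px: float = 60.0
    stickiness_beta: float = 0.8
    judgement_window_s: float = 2.0
    no_agency_cutoff_px: float = 4.0
    aq_score: int = 21
    blink_rate_hz: float = 0.2
    gaze_noise_sd_px: float = 8.0

    def __post_init__(self):
        if len(self.policy_weights) != 6 or any(w < 0 for w in self.policy_weights):
            raise ValueError("policy_weights must be 6 non-negative values")
        if sum(self.policy_weights) <= 0:
            raise ValueError("policy_weights must be normalisable")
        if self.switch_threshold_px <= 0:
            raise ValueError("switch_threshold_px must be positive")
        if not 0 < self.stickiness_beta <= 1:
            raise ValueError("stickiness_beta must be in (0, 1]")
        if not 0 <= self.aq_score <= 50:
            raise ValueError("aq_score must be in [0, 50]")


_POLICY_ORDER = (
    "Horizontal",
    "Vertical",
    "PerpendicularCardinal",
    "NonCardinal",
    "HesitantStraight",
    "Circle",
)


@dataclass
class MouseTraceTruth:
    """Ground-truth annotations emitted alongside a generated trace."""

    raw_turns: list[tuple[int, int, int]]  # (onset frame, dir_from, dir_to)
    events: list[tuple[int, str]]  # (onset frame, policy label)


def sample_aq(rng) -> int:
    """AQ covariate: Normal(21.43, 5.89) truncated to [0, 50], rounded."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    while True:
        v = rng.normal(AQ_MEAN, AQ_SD)
        if 0 <= v <= 50:
            return int(round(v))


def _unit(direction: int) -> np.ndarray:
    theta = np.radians(45.0 * direction)
    return np.array([np.cos(theta), np.sin(theta)])


def generate_mouse_trace(
    profile: AgentProfile, cfg: TaskConfig, seed
) -> tuple[np.ndarray, MouseTraceTruth]:
    """Piecewise-constant-direction mouse trace with annotated turns.

    Direction segments last >= 3 frames; turn types are drawn from the
    profile's policy weights.  Returns the (F, 2) displacement trace and the
    ground-truth turn/policy annotations (truncated events near the trial end
    are dropped so every annotated turn is detectable).
    """
    rng = np.random.default_rng(seed)
    F = cfg.frames_per_trial
    w = np.asarray(profile.policy_weights, float)
    w = w / w.sum()
    speed = profile.base_speed_px_per_frame

    segments: list[tuple[int | None, int]] = []  # (direction or None=pause, length)
    raw_turns: list[tuple[int, int, int]] = []
    events: list[tuple[int, str]] = []

    # start on an axis compatible with the first drawn policy so degenerate
    # weight vectors (e.g. all-Horizontal) yield only that policy's turns
    first_policy = _POLICY_ORDER[int(rng.choice(6, p=w))]
    start_dirs = {
        "Horizontal": (0, 4),
        "Vertical": (2, 6),
        "NonCardinal": _DIAGONALS,
        "Circle": _CARDINALS + _DIAGONALS,
    }.get(first_policy, _CARDINALS)
    cur = int(rng.choice(start_dirs))
    t = 0

    def push(direction: int | None, length: int):
        nonlocal t
        segments.append((direction, length))
        t += length

    def seg_len() -> int:
        return int(rng.integers(6, 25))

    def turn_to(new: int, label: str | None = None):
        nonlocal cur
        raw_turns.append((t, cur, new))
        events.append((t, label or classify_turn_policy(cur, new)))
        cur = new
        push(cur, seg_len())

    push(cur, seg_len())
    while t < F + 40:
        if rng.random() < profile.pause_prob:
            push(None, int(rng.integers(3, 13)))
        policy = _POLICY_ORDER[int(rng.choice(6, p=w))]
        if policy == "Horizontal":
            new = (cur + 4) % 8 if cur in (0, 4) else int(rng.choice([0, 4]))
            turn_to(new)
        elif policy == "Vertical":
            new = (cur + 4) % 8 if cur in (2, 6) else int(rng.choice([2, 6]))
            turn_to(new)
        elif policy == "PerpendicularCardinal":
            if cur % 2 == 0:
                new = (cur + int(rng.choice([-2, 2]))) % 8
            else:
                new = int(rng.choice([c for c in _CARDINALS]))
            turn_to(new)
        elif policy == "NonCardinal":
            new = int(rng.choice([d for d in _DIAGONALS if d != cur]))
            turn_to(new)
        elif policy == "HesitantStraight":
            push(None, int(rng.integers(3, 13)))
            events.append((t, "HesitantStraight"))
            push(cur, seg_len())
        else:  # Circle: run of same-rotation 45-degree turns inside 30 frames
            rot = int(rng.choice([-1, 1]))
            k = int(rng.integers(4, 7))
            start = t
            first = True
            for _ in range(k):
                new = (cur + rot) % 8
                raw_turns.append((t, cur, new))
                cur = new
                push(cur, int(rng.integers(3, 5)))
                if first:
                    events.append((start, "Circle"))
                    first = False

    # materialise and truncate to the trial length
    trace = np.zeros((F, 2))
    pos = 0
    for direction, length in segments:
        if pos >= F:
            break
        end = min(pos + length, F)
        if direction is not None:
            trace[pos:end] = speed * _unit(direction)
        pos = end
    raw_turns = [rt for rt in raw_turns if rt[0] <= F - 3]
    events = [ev for ev in events if ev[0] <= F - 3]
    return trace, MouseTraceTruth(raw_turns=raw_turns, events=events)


@dataclass
class GazeAgentResult:
    gaze_xy: np.ndarray  # (F, 2) fixated point (hypothesised square centre)
    hypothesis: np.ndarray  # (F,) square index
    switch_frames: np.ndarray  # ground-truth switch onsets
    response: int  # 0 = judged no control, else square index + 1


def simulate_gaze_agent(
    trial: TrialLog, profile: AgentProfile, seed
) -> GazeAgentResult:
    """Threshold-switching gaze agent.

    The agent fixates the centroid of one hypothesised square; that square's
    one-step prediction error feeds a leaky accumulator.  When the
    accumulator crosses ``switch_threshold_px`` the agent switches to the
    square with the lowest recent one-step prediction error (refractory
    period 12 frames).  The agency judgement uses the per-square mean
    prediction error over the final judgement window.
    """
    rng = np.random.default_rng(seed)
    F = trial.n_frames
    pe_all = per_square_prediction_error(trial)  # (F, n)
    n = pe_all.shape[1]

    hyp = int(rng.integers(n))
    acc = 0.0
    refractory = 0
    hyp_seq = np.empty(F, dtype=int)
    switches = []
    for t in range(F):
        acc = ACCUMULATOR_DECAY * acc + pe_all[t, hyp]
        if refractory > 0:
            refractory -= 1
        elif acc > profile.switch_threshold_px:
            recent = pe_all[max(0, t - RECENT_PE_FRAMES + 1) : t + 1].mean(axis=0)
            new = int(np.argmin(recent))
            if new != hyp:
                switches.append(t)
                hyp = new
            acc = 0.0
            refractory = SWITCH_REFRACTORY_FRAMES
        hyp_seq[t] = hyp

    gaze = trial.square_xy[np.arange(F), hyp_seq]
    response = judge_agency(
        _window_pe(pe_all, trial, profile), profile
    )
    return GazeAgentResult(
        gaze_xy=gaze,
        hypothesis=hyp_seq,
        switch_frames=np.asarray(switches, int),
        response=response,
    )


def _window_pe(pe_all: np.ndarray, trial: TrialLog, profile: AgentProfile) -> np.ndarray:
    """Per-square PE evidence over the final judgement window, restricted to
    moving frames (stationary frames carry no information)."""
    w = int(round(profile.judgement_window_s * trial.cfg.fps))
    window = pe_all[-w:]
    speed = np.hypot(trial.mouse_dxy[-w:, 0], trial.mouse_dxy[-w:, 1])
    moving = speed > 0
    return window[moving] if moving.any() else window


def judge_agency(pe_by_square: np.ndarray, profile: AgentProfile) -> int:
    """Agency judgement from per-square prediction-error evidence.

    Returns ``square index + 1`` of the arg-min mean PE square when that
    minimum is below the no-agency cutoff, else 0 ("I controlled none").
    """
    pe_by_square = np.atleast_2d(np.asarray(pe_by_square, float))
    if pe_by_square.size == 0:
        raise ValueError("empty evidence window")
    with np.errstate(invalid="ignore"):
        means = np.nanmean(pe_by_square, axis=0)
    best = int(np.nanargmin(means))
    return best + 1 if means[best] < profile.no_agency_cutoff_px else 0


def inject_eye_noise(
    gaze_xy: np.ndarray,
    profile: AgentProfile,
    seed,
    native_rate: float = 1000.0,
    fps: float = 60.0,
    screen: tuple[float, float] = (1920.0, 1080.0),
    pupil_baseline: float = 1000.0,
    pupil_noise_sd: float = 15.0,
) -> tuple[EyeTrace, dict]:
    """Raw binocular eye trace from a frame-rate ground-truth gaze path.

    Upsamples to ``native_rate`` (sample-and-hold per frame), adds Gaussian
    gaze noise and a fixed binocular disparity, injects Poisson-timed blinks
    (pupil collapse plus gaze dropout, 100-300 ms, shared across eyes) and
    occasional brief off-screen excursions.  Returns the trace and an info
    dict with the injected artifact ground truth.
    """
    rng = np.random.default_rng(seed)
    gaze_xy = np.asarray(gaze_xy, float)
    F = gaze_xy.shape[0]
    duration = F / fps
    n = int(round(duration * native_rate))
    t = (np.arange(n) + 0.5) / native_rate
    frame_of = np.minimum((t * fps).astype(int), F - 1)
    gt = gaze_xy[frame_of]

    disparity = np.array([4.0, 0.0])
    noise = profile.gaze_noise_sd_px
    xl = gt[:, 0] + rng.normal(0, noise, n)
    yl = gt[:, 1] + rng.normal(0, noise, n)
    xr = gt[:, 0] + disparity[0] + rng.normal(0, noise, n)
    yr = gt[:, 1] + disparity[1] + rng.normal(0, noise, n)
    pl = pupil_baseline + rng.normal(0, pupil_noise_sd, n)
    pr = pupil_baseline + rng.normal(0, pupil_noise_sd, n)

    n_blinks = rng.poisson(profile.blink_rate_hz * duration)
    blink_spans = []
    for _ in range(n_blinks):
        dur = rng.uniform(0.100, 0.300)
        onset = rng.uniform(0, max(duration - dur, 0))
        a = int(onset * native_rate)
        b = min(int((onset + dur) * native_rate), n)
        if a >= b:
            continue
        blink_spans.append((a, b))
        for x_, y_, p_ in ((xl, yl, pl), (xr, yr, pr)):
            p_[a:b] = pupil_baseline * 0.05
            x_[a:b] = -3000.0
            y_[a:b] = -3000.0

    n_exc = rng.poisson(0.05 * duration)
    for _ in range(n_exc):
        a = int(rng.uniform(0, n - 40))
        b = a + int(rng.uniform(10, 40))
        xl[a:b] = -10.0
        xr[a:b] = -10.0

    trace = EyeTrace(
        t=t, x_left=xl, y_left=yl, pupil_left=pl,
        x_right=xr, y_right=yr, pupil_right=pr,
    )
    return trace, {"blink_spans": blink_spans, "n_blinks": len(blink_spans), "n_excursions": int(n_exc)}
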