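"""Stimulus engine for the squares task.

Eight squares share a single input vector (the mouse displacement).  One
square — the target — follows the mouse up to angular jitter; the other
seven carry an additional per-distractor angular offset that is redrawn a
fixed number of times per trial.  The width of the jitter distribution
(``variability``) alternates between a narrow and a wide state on a
pseudo-random schedule (``volatility``).

Conventions
-----------
* Coordinates: origin top-left, x rightward, y downward, units pixels.
* Angles: degrees, measured from +x, clockwise positive (y-down screen).
* Frames are 0-based; time in seconds is ``frame / fps``.
* The screen is toroidal: positions wrap modulo (screen_w, screen_h).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats as _sstats

# Two-sided 95% interval half-width of a standard normal, used to map a
# configured CI half-width onto the jitter SD.
Z95 = float(_sstats.norm.ppf(0.975))

VARIABILITY_CI_PAIRS = {"low": (10.0, 30.0), "high": (90.0, 110.0)}
VOLATILITY_CHANGES = {"low": 3, "high": 10}

__all__ = [
    "TaskConfig",
    "VolatilitySchedule",
    "TrialLog",
    "make_volatility_schedule",
    "sample_jitter_angle",
    "make_distractor_offsets",
    "step_squares",
    "simulate_trial",
    "build_experiment_schedule",
    "wrap_delta",
    "wrap_distance",
    "Z95",
]


@dataclass(frozen=True)
class TaskConfig:
    """Parameters of a single trial of the squares task."""

    frames_per_trial: int = 900
    fps: float = 60.0
    n_squares: int = 8
    square_size_px: float = 100.0
    screen_w: float = 1920.0
    screen_h: float = 1080.0
    variability_level: str = "low"
    volatility_level: str = "low"
    ci_pair_deg: tuple[float, float] | None = None
    n_volatility_changes: int | None = None
    min_change_gap_frames: int = 50
    distractor_redraws: int = 5
    offset_transition_frames: int = 30
    min_start_separation_px: float = 120.0

    def __post_init__(self) -> None:
        if self.variability_level not in VARIABILITY_CI_PAIRS:
            raise ValueError(f"unknown variability level {self.variability_level!r}")
        if self.volatility_level not in VOLATILITY_CHANGES:
            raise ValueError(f"unknown volatility level {self.volatility_level!r}")
        if self.ci_pair_deg is None:
            object.__setattr__(
                self, "ci_pair_deg", VARIABILITY_CI_PAIRS[self.variability_level]
            )
        if self.n_volatility_changes is None:
            object.__setattr__(
                self, "n_volatility_changes", VOLATILITY_CHANGES[self.volatility_level]
            )
        lo, hi = self.ci_pair_deg
        if not (0.0 < lo < hi):
            raise ValueError("ci_pair_deg must be strictly positive and ordered")
        if self.frames_per_trial != round(15 * self.fps):
            raise ValueError("frames_per_trial must equal 15 s x fps")
        if self.n_volatility_changes * self.min_change_gap_frames >= self.frames_per_trial:
            raise ValueError("volatility changes do not fit in the trial")

    @property
    def trial_seconds(self) -> float:
        return self.frames_per_trial / self.fps

    @property
    def condition(self) -> tuple[str, str]:
        return (self.variability_level, self.volatility_level)

    def with_condition(self, variability: str, volatility: str) -> "TaskConfig":
        return replace(
            self,
            variability_level=variability,
            volatility_level=volatility,
            ci_pair_deg=VARIABILITY_CI_PAIRS[variability],
            n_volatility_changes=VOLATILITY_CHANGES[volatility],
        )


@dataclass(frozen=True)
class VolatilitySchedule:
    """Alternating narrow/wide jitter states with pseudo-random change frames."""

    change_frames: np.ndarray  # sorted frame indices, int
    state_per_frame: np.ndarray  # array of "narrow"/"wide", one per frame
    start_state: str

    @property
    def n_changes(self) -> int:
        return int(len(self.change_frames))


@dataclass
class TrialLog:
    """Complete per-frame record of one simulated trial.

    ``square_xy[f, s]`` is the (wrapped) position of square ``s`` at the end
    of frame ``f`` (after the frame-``f`` displacement).  ``initial_xy`` is
    the placement before any movement.
    """

    trial_id: int
    cfg: TaskConfig
    is_no_control: bool
    target_index: int | None
    rng_seed: int
    mouse_dxy: np.ndarray  # (F, 2)
    square_xy: np.ndarray  # (F, n_squares, 2)
    initial_xy: np.ndarray  # (n_squares, 2)
    jitter_state: np.ndarray  # (F,) of "narrow"/"wide"
    offset_deg: np.ndarray  # (F, n_squares); NaN for the target column
    schedule: VolatilitySchedule
    participant: int | None = None
    block: int | None = None
    jitter_deg: np.ndarray | None = None  # (F, n_squares) draws actually applied

    @property
    def n_frames(self) -> int:
        return int(self.mouse_dxy.shape[0])

    def positions_before(self) -> np.ndarray:
        """Positions at the start of each frame: (F, n_squares, 2)."""
        return np.concatenate(
            [self.initial_xy[None, :, :], self.square_xy[:-1]], axis=0
        )

    @property
    def ci_narrow_deg(self) -> float:
        return float(self.cfg.ci_pair_deg[0])

    @property
    def ci_wide_deg(self) -> float:
        return float(self.cfg.ci_pair_deg[1])


def wrap_delta(a: np.ndarray, b: np.ndarray, period: np.ndarray) -> np.ndarray:
    """Minimum-image difference ``a - b`` on a torus with the given periods."""
    d = np.asarray(a, float) - np.asarray(b, float)
    period = np.asarray(period, float)
    return d - period * np.round(d / period)


def wrap_distance(a: np.ndarray, b: np.ndarray, period: np.ndarray) -> np.ndarray:
    """Wrap-aware Euclidean distance between points on the torus."""
    return np.linalg.norm(wrap_delta(a, b, period), axis=-1)


def _sample_gapped_frames(
    rng: np.random.Generator, n: int, lo: int, hi: int, gap: int, batch: int = 4096
) -> np.ndarray:
    """Uniform rejection sampling of ``n`` sorted frames in [lo, hi) with all
    consecutive gaps >= ``gap``.  Vectorised over candidate sets."""
    if n == 0:
        return np.zeros(0, dtype=int)
    if lo + (n - 1) * gap >= hi:
        raise ValueError("infeasible schedule: gap x changes exceeds trial length")
    while True:
        cand = rng.integers(lo, hi, size=(batch, n))
        cand.sort(axis=1)
        if n == 1:
            return cand[0]
        ok = np.all(np.diff(cand, axis=1) >= gap, axis=1)
        idx = np.flatnonzero(ok)
        if idx.size:
            return cand[idx[0]]


def make_volatility_schedule(cfg: TaskConfig, seed) -> VolatilitySchedule:
    """Place ``cfg.n_volatility_changes`` state changes pseudo-randomly with a
    minimum inter-change gap, alternating from a random start state."""
    rng = np.random.default_rng(seed)
    gap = cfg.min_change_gap_frames
    changes = _sample_gapped_frames(
        rng, cfg.n_volatility_changes, gap, cfg.frames_per_trial, gap
    )
    start_state = "narrow" if rng.random() < 0.5 else "wide"
    states = np.array(["narrow", "wide"])
    start_idx = 0 if start_state == "narrow" else 1
    flips = np.zeros(cfg.frames_per_trial, dtype=int)
    flips[changes] = 1
    state_idx = (start_idx + np.cumsum(flips)) % 2
    return VolatilitySchedule(
        change_frames=changes.astype(int),
        state_per_frame=states[state_idx],
        start_state=start_state,
    )


def sample_jitter_angle(ci_halfwidth_deg: float, rng, size=None) -> np.ndarray | float:
    """Zero-mean Gaussian angular jitter whose two-sided 95% interval
    half-width equals ``ci_halfwidth_deg``."""
    if ci_halfwidth_deg <= 0:
        raise ValueError("ci_halfwidth_deg must be positive")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    sd = ci_halfwidth_deg / Z95
    return rng.normal(0.0, sd, size=size)


def _shortest_arc_delta(frm: np.ndarray, to: np.ndarray) -> np.ndarray:
    return (np.asarray(to, float) - np.asarray(frm, float) + 180.0) % 360.0 - 180.0


def make_distractor_offsets(
    cfg: TaskConfig, n_distractors: int, seed
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Per-frame angular offsets for each distractor.

    Each distractor starts at an offset uniform on [0, 360) and is redrawn at
    ``cfg.distractor_redraws`` pseudo-random frames, transitioning along the
    shortest arc over ``cfg.offset_transition_frames`` frames.  Returns the
    (F, n_distractors) offset array (degrees, mod 360) and the per-distractor
    redraw-onset frames.
    """
    rng = np.random.default_rng(seed)
    F = cfg.frames_per_trial
    T = cfg.offset_transition_frames
    out = np.zeros((F, n_distractors))
    onsets: list[np.ndarray] = []
    for d in range(n_distractors):
        values = rng.uniform(0.0, 360.0, size=cfg.distractor_redraws + 1)
        if cfg.distractor_redraws > 0:
            # keep redraw windows disjoint so every redraw is a distinct turn
            frames = _sample_gapped_frames(
                rng,
                cfg.distractor_redraws,
                max(T, 1),
                F - max(T, 1),
                max(T, 1),
            )
        else:
            frames = np.zeros(0, dtype=int)
        trace = np.full(F, values[0])
        for k, f in enumerate(frames):
            old = trace[f - 1] if f > 0 else values[k]
            delta = _shortest_arc_delta(old, values[k + 1])
            if T <= 0:
                trace[f:] = old + delta
            else:
                ramp = old + delta * np.arange(1, T + 1) / T
                end = min(f + T, F)
                trace[f:end] = ramp[: end - f]
                trace[end:] = old + delta
        out[:, d] = trace % 360.0
        onsets.append(frames)
    return out, onsets


def step_squares(
    positions: np.ndarray,
    mouse_dx: float,
    mouse_dy: float,
    jitter_draws: np.ndarray,
    offsets: np.ndarray,
    screen: tuple[float, float] = (1920.0, 1080.0),
) -> np.ndarray:
    """Advance all squares by one frame.

    Every square moves by the mouse displacement *magnitude*; its direction is
    the mouse angle plus its angular offset plus its jitter draw (degrees).
    Zero mouse displacement leaves every square in place.
    """
    positions = np.asarray(positions, float)
    mag = float(np.hypot(mouse_dx, mouse_dy))
    if mag == 0.0:
        return positions.copy()
    ang = np.degrees(np.arctan2(mouse_dy, mouse_dx))
    theta = np.radians(ang + np.asarray(offsets, float) + np.asarray(jitter_draws, float))
    disp = mag * np.stack([np.cos(theta), np.sin(theta)], axis=-1)
    return (positions + disp) % np.asarray(screen, float)


def _initial_placement(cfg: TaskConfig, rng: np.random.Generator) -> np.ndarray:
    """Uniform random placement with a minimum centre separation."""
    for _ in range(10_000):
        xy = rng.uniform(
            [0.0, 0.0], [cfg.screen_w, cfg.screen_h], size=(cfg.n_squares, 2)
        )
        d = wrap_distance(
            xy[:, None, :], xy[None, :, :], np.array([cfg.screen_w, cfg.screen_h])
        )
        np.fill_diagonal(d, np.inf)
        if d.min() >= cfg.min_start_separation_px:
            return xy
    raise RuntimeError("could not place squares with the requested separation")


def simulate_trial(
    cfg: TaskConfig,
    mouse_trace: np.ndarray,
    is_no_control: bool,
    seed,
    trial_id: int = 0,
    participant: int | None = None,
    block: int | None = None,
) -> TrialLog:
    """Simulate one complete trial from a per-frame mouse displacement trace.

    Vectorised over frames; equivalent to iterating :func:`step_squares` with
    per-frame jitter draws (jitter is consumed only on moving frames).
    """
    mouse_trace = np.asarray(mouse_trace, float)
    if mouse_trace.shape != (cfg.frames_per_trial, 2):
        raise ValueError(
            f"mouse trace must have shape ({cfg.frames_per_trial}, 2), "
            f"got {mouse_trace.shape}"
        )
    if isinstance(seed, np.random.SeedSequence):
        seed = int(seed.generate_state(1)[0])
    elif not isinstance(seed, (int, np.integer)):
        seed = int(np.random.SeedSequence(seed).generate_state(1)[0])
    seed = int(seed)
    rng = np.random.default_rng(seed)
    F, n = cfg.frames_per_trial, cfg.n_squares
    screen = np.array([cfg.screen_w, cfg.screen_h])

    schedule = make_volatility_schedule(cfg, rng)
    init = _initial_placement(cfg, rng)

    if is_no_control:
        target = None
        offsets_all, _ = make_distractor_offsets(cfg, n, rng)
    else:
        target = int(rng.integers(n))
        dist_offsets, _ = make_distractor_offsets(cfg, n - 1, rng)
        offsets_all = np.zeros((F, n))
        cols = [s for s in range(n) if s != target]
        offsets_all[:, cols] = dist_offsets

    speed = np.hypot(mouse_trace[:, 0], mouse_trace[:, 1])
    moving = speed > 0.0
    ang = np.zeros(F)
    ang[moving] = np.degrees(np.arctan2(mouse_trace[moving, 1], mouse_trace[moving, 0]))

    ci = np.where(schedule.state_per_frame == "narrow", *cfg.ci_pair_deg)
    sd = ci / Z95
    jitter = np.zeros((F, n))
    jitter[moving] = rng.standard_normal((int(moving.sum()), n)) * sd[moving, None]

    theta = np.radians(ang[:, None] + offsets_all + jitter)
    disp = speed[:, None, None] * np.stack([np.cos(theta), np.sin(theta)], axis=-1)
    disp[~moving] = 0.0
    positions = (init[None] + np.cumsum(disp, axis=0)) % screen

    offset_log = offsets_all.copy()
    if target is not None:
        offset_log[:, target] = np.nan

    return TrialLog(
        trial_id=trial_id,
        cfg=cfg,
        is_no_control=is_no_control,
        target_index=target,
        rng_seed=seed,
        mouse_dxy=mouse_trace,
        square_xy=positions,
        initial_xy=init,
        jitter_state=schedule.state_per_frame,
        offset_deg=offset_log,
        schedule=schedule,
        participant=participant,
        block=block,
        jitter_deg=jitter,
    )


@dataclass(frozen=True)
class TrialPlan:
    block: int
    trial: int
    variability: str
    volatility: str
    is_no_control: bool


def build_experiment_schedule(
    seed,
    blocks_per_condition: int = 2,
    trials_per_block: int = 18,
    no_control_per_block: int = 2,
) -> list[TrialPlan]:
    """Ordered trial plan for one participant: ``blocks_per_condition`` blocks
    of each 2x2 condition, each with ``trials_per_block`` trials of which
    ``no_control_per_block`` are no-control, block order and no-control
    positions shuffled."""
    rng = np.random.default_rng(seed)
    conditions = [
        (var, vol) for var in ("low", "high") for vol in ("low", "high")
    ] * blocks_per_condition
    rng.shuffle(conditions)
    plan: list[TrialPlan] = []
    for b, (var, vol) in enumerate(conditions):
        flags = np.zeros(trials_per_block, dtype=bool)
        flags[rng.choice(trials_per_block, size=no_control_per_block, replace=False)] = True
        for t in range(trials_per_block):
            plan.append(TrialPlan(b, t, var, vol, bool(flags[t])))
    return plan
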