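"""Looked-at-square assignment, hypothesis switches, the prediction-error
proxy, its slopes, and event-related prediction error (ERPE).

The prediction error is one-step-ahead: the expected position of the
hypothesised square at frame t is its own actual position at t-1 plus the
mouse displacement at t; the error is the wrap-aware Euclidean distance to
its actual position at t.  A cumulative-from-start variant is available
behind a flag for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .task import TrialLog, wrap_delta, wrap_distance

STICKINESS_BETA = 0.8  # incumbent square's distance is scaled by this
EPOCH_HALF_FRAMES = 30  # 500 ms at 60 Hz on each side of the event
N_BINS = 5
BIN_FRAMES = 12  # 200 ms at 60 Hz

__all__ = [
    "HypothesisTrack",
    "PESeries",
    "assign_looked_square",
    "assign_hypotheses",
    "detect_hypothesis_switches",
    "per_square_prediction_error",
    "prediction_error_series",
    "pe_slope",
    "erpe_epochs",
    "STICKINESS_BETA",
]


@dataclass
class HypothesisTrack:
    looked_square: np.ndarray  # (F,) int, -1 where no hypothesis yet
    switch_frames: np.ndarray  # onset frames of persistent changes

    @property
    def n_switches(self) -> int:
        return int(len(self.switch_frames))


@dataclass
class PESeries:
    pe_px: np.ndarray  # (F,) float, NaN where no hypothesis
    trial_mean: float
    looked_square: np.ndarray
    condition: tuple[str, str] | None = None

    @property
    def n_frames(self) -> int:
        return len(self.pe_px)


def assign_looked_square(
    gaze_xy: np.ndarray,
    square_xy: np.ndarray,
    previous: int | None,
    beta: float = STICKINESS_BETA,
    screen: tuple[float, float] = (1920.0, 1080.0),
) -> int | None:
    """Biased-nearest-object assignment for a single frame.

    The nearest square centroid wins, except that the incumbent square's
    distance is multiplied by ``beta <= 1`` (stickiness).  An invalid gaze
    (any NaN) carries the previous assignment forward.
    """
    gaze_xy = np.asarray(gaze_xy, float)
    if not np.all(np.isfinite(gaze_xy)):
        return previous
    d = wrap_distance(gaze_xy[None, :], np.asarray(square_xy, float), np.asarray(screen))
    if previous is not None and 0 <= previous < len(d):
        d = d.copy()
        d[previous] *= beta
    return int(np.argmin(d))


def assign_hypotheses(
    gaze_x: np.ndarray,
    gaze_y: np.ndarray,
    square_xy: np.ndarray,
    beta: float = STICKINESS_BETA,
    screen: tuple[float, float] = (1920.0, 1080.0),
) -> np.ndarray:
    """Frame-wise looked-square assignment over a trial (-1 before the first
    valid gaze frame).  ``square_xy`` is (F, n_squares, 2)."""
    F = len(gaze_x)
    gaze = np.stack([np.asarray(gaze_x, float), np.asarray(gaze_y, float)], axis=-1)
    valid = np.all(np.isfinite(gaze), axis=-1)
    # precompute all distances at once; the stickiness bias needs the loop
    d_all = wrap_distance(
        gaze[:, None, :], np.asarray(square_xy, float), np.asarray(screen, float)
    )
    out = np.full(F, -1, dtype=int)
    prev: int | None = None
    for t in range(F):
        if not valid[t]:
            out[t] = -1 if prev is None else prev
            continue
        d = d_all[t]
        if prev is not None:
            d = d.copy()
            d[prev] *= beta
        prev = int(np.argmin(d))
        out[t] = prev
    return out


def detect_hypothesis_switches(looked: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Switch onsets in a looked-square sequence.

    Single-frame flickers are merged back into the surrounding assignment; a
    change persisting >= 2 frames is a switch at its onset frame.  Returns
    ``(switch_frames, deflickered_sequence)``.
    """
    looked = np.asarray(looked, int).copy()
    F = len(looked)
    # merge 1-frame flickers: value differs from both neighbours
    for t in range(1, F - 1):
        if looked[t] != looked[t - 1] and looked[t] != looked[t + 1]:
            looked[t] = looked[t - 1]
    if F >= 2 and looked[-1] != looked[-2]:
        looked[-1] = looked[-2]  # trailing 1-frame run cannot persist
    change = np.flatnonzero(np.diff(looked) != 0) + 1
    change = change[looked[change] >= 0]
    if len(change) and looked[change[0] - 1] < 0:
        change = change[1:]  # first acquisition is not a switch
    return change, looked


def per_square_prediction_error(trial: TrialLog) -> np.ndarray:
    """One-step prediction error for every square at every frame: (F, n).

    pe[t, s] = wrap-distance( pos[t-1, s] + mouse[t], pos[t, s] ).
    """
    screen = np.array([trial.cfg.screen_w, trial.cfg.screen_h])
    prev = trial.positions_before()
    expected = prev + trial.mouse_dxy[:, None, :]
    return wrap_distance(expected, trial.square_xy, screen)


def prediction_error_series(
    trial: TrialLog,
    track: HypothesisTrack | np.ndarray,
    cumulative: bool = False,
) -> PESeries:
    """Per-frame prediction error of the hypothesised square.

    With ``cumulative=True`` the expectation integrates the mouse path from
    the frame the current hypothesis was adopted (divergence-style), instead
    of the one-step formulation.
    """
    looked = track.looked_square if isinstance(track, HypothesisTrack) else np.asarray(track, int)
    F = trial.n_frames
    if len(looked) != F:
        raise ValueError("hypothesis track length mismatch")
    screen = np.array([trial.cfg.screen_w, trial.cfg.screen_h])
    pe = np.full(F, np.nan)
    has = looked >= 0
    if not cumulative:
        pe_all = per_square_prediction_error(trial)
        pe[has] = pe_all[np.flatnonzero(has), looked[has]]
    else:
        prev = trial.positions_before()
        expected = np.full((F, 2), np.nan)
        for t in range(F):
            s = looked[t]
            if s < 0:
                continue
            if t == 0 or looked[t - 1] != s or np.isnan(expected[t - 1]).any():
                base = prev[t, s]
            else:
                base = expected[t - 1]
            expected[t] = (base + trial.mouse_dxy[t]) % screen
            pe[t] = wrap_distance(expected[t], trial.square_xy[t, s], screen)
    mean = float(np.nanmean(pe)) if has.any() else float("nan")
    return PESeries(pe_px=pe, trial_mean=mean, looked_square=looked, condition=trial.cfg.condition)


def pe_slope(pe_table: pd.DataFrame, cell_cols: list[str], fps: float = 60.0) -> pd.DataFrame:
    """OLS slope of mean prediction error against time within cells.

    ``pe_table`` is long-form with columns {participant, trial, frame, pe_px}
    plus the ``cell_cols`` labels.  Within each (participant, *cell*) group,
    prediction error is averaged across trials at each frame and a line is
    fitted against time in seconds.  Cells with < 2 valid time points get NaN.
    """
    required = {"participant", "trial", "frame", "pe_px", *cell_cols}
    missing = required - set(pe_table.columns)
    if missing:
        raise ValueError(f"pe table missing columns: {sorted(missing)}")
    rows = []
    for keys, grp in pe_table.groupby(["participant", *cell_cols], sort=True):
        mean_by_frame = grp.groupby("frame")["pe_px"].mean().dropna()
        rec = dict(zip(["participant", *cell_cols], keys))
        if len(mean_by_frame) < 2:
            rec.update(slope=np.nan, intercept=np.nan, n_frames=len(mean_by_frame))
        else:
            t = mean_by_frame.index.to_numpy(float) / fps
            coef = np.polyfit(t, mean_by_frame.to_numpy(float), 1)
            rec.update(slope=float(coef[0]), intercept=float(coef[1]), n_frames=len(mean_by_frame))
        rows.append(rec)
    return pd.DataFrame(rows)


def erpe_epochs(
    pe_px: np.ndarray,
    event_frames: np.ndarray,
    half: int = EPOCH_HALF_FRAMES,
    n_bins: int = N_BINS,
) -> tuple[np.ndarray, np.ndarray]:
    """Event-centred prediction-error epochs reduced to bin means.

    Each epoch spans frames [event - half, event + half), tiled by ``n_bins``
    equal bins; the middle bin is centred on the event onset.  Events closer
    than ``half`` frames to either trial edge are dropped.  Returns
    ``(epochs, bin_means)`` of shapes (n_events, 2*half) and
    (n_events, n_bins); NaN prediction-error frames are excluded from means.
    """
    pe_px = np.asarray(pe_px, float)
    events = np.asarray(event_frames, int)
    F = len(pe_px)
    keep = (events >= half) & (events <= F - half)
    events = events[keep]
    if len(events) == 0:
        return np.zeros((0, 2 * half)), np.zeros((0, n_bins))
    idx = events[:, None] + np.arange(-half, half)[None, :]
    epochs = pe_px[idx]
    bins = epochs.reshape(len(events), n_bins, (2 * half) // n_bins)
    with np.errstate(invalid="ignore"):
        bin_means = np.nanmean(bins, axis=2)
    return epochs, bin_means
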