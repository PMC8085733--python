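"""Cleaning of raw binocular eye traces and alignment to stimulus frames.

Pipeline per trial: flag blinks from pupil excursions, invalidate off-screen
samples, linearly interpolate the gaps, smooth with a 15-sample Hanning
window (stride 1, reflected edges), merge the two eyes, and average samples
within each stimulus frame.  Trials with too much interpolation in both eyes
or an outlying recorded length are flagged for exclusion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

BLINK_LOW_SD = 1.5  # flag pupil < mean - 1.5 sd (strict)
BLINK_HIGH_SD = 2.0  # flag pupil > mean + 2 sd (strict)
HANNING_SAMPLES = 15
POOR_TRIAL_INTERP_FRAC = 0.30  # exclusion when exceeded in BOTH eyes
SINGLE_EYE_BAD_FRAC = 0.35  # whole-trial substitution when one eye above ...
SINGLE_EYE_GOOD_FRAC = 0.15  # ... and the other below

__all__ = [
    "EyeTrace",
    "FrameGaze",
    "pupil_stats",
    "detect_blinks",
    "clean_and_smooth",
    "merge_and_downsample",
    "flag_poor_trials",
]


@dataclass
class EyeTrace:
    """Raw or cleaned binocular samples.  Gaze in px, pupil in arbitrary
    units; NaN marks missing samples."""

    t: np.ndarray
    x_left: np.ndarray
    y_left: np.ndarray
    pupil_left: np.ndarray
    x_right: np.ndarray
    y_right: np.ndarray
    pupil_right: np.ndarray
    interpolated_left: np.ndarray | None = None
    interpolated_right: np.ndarray | None = None

    def __post_init__(self):
        n = len(self.t)
        for name in ("x_left", "y_left", "pupil_left", "x_right", "y_right", "pupil_right"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"length mismatch in {name}")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("sample times must be strictly increasing")

    @property
    def n_samples(self) -> int:
        return len(self.t)

    def eye(self, side: str):
        return (
            getattr(self, f"x_{side}"),
            getattr(self, f"y_{side}"),
            getattr(self, f"pupil_{side}"),
        )


@dataclass
class FrameGaze:
    """Gaze merged across eyes and binned to stimulus frames."""

    gaze_x: np.ndarray  # (F,)
    gaze_y: np.ndarray
    valid: np.ndarray  # (F,) bool
    frac_interp_left: float
    frac_interp_right: float
    substituted_eye: str | None = None  # eye used alone for the whole trial

    @property
    def n_frames(self) -> int:
        return len(self.gaze_x)


def pupil_stats(pupils: list[np.ndarray] | np.ndarray) -> tuple[float, float]:
    """Mean and SD of pupil size over all non-missing samples (single pass,
    typically pooled over a participant's whole session)."""
    if isinstance(pupils, list):
        pupils = np.concatenate([np.asarray(p, float) for p in pupils])
    pupils = np.asarray(pupils, float)
    valid = pupils[np.isfinite(pupils)]
    if valid.size == 0:
        raise ValueError("no valid pupil samples")
    return float(valid.mean()), float(valid.std())


def _spans_from_mask(mask: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous True runs as half-open (start, stop) index pairs."""
    mask = np.asarray(mask, bool)
    if not mask.any():
        return []
    d = np.diff(mask.astype(int))
    starts = list(np.flatnonzero(d == 1) + 1)
    stops = list(np.flatnonzero(d == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        stops.append(len(mask))
    return list(zip(starts, stops))


def detect_blinks(
    trace: EyeTrace, stats: tuple[float, float] | None = None
) -> dict[str, list[tuple[int, int]]]:
    """Blink spans per eye from pupil excursions.

    A sample is blink-flagged when its pupil is strictly below mean - 1.5 SD
    or strictly above mean + 2 SD of the participant's pupil distribution
    (``stats``; computed from this trace when not supplied).  Missing pupil
    samples are flagged too.  Contiguous flags merge into spans.
    """
    spans = {}
    for side in ("left", "right"):
        pupil = np.asarray(trace.eye(side)[2], float)
        mu, sd = stats if stats is not None else pupil_stats(pupil)
        bad = ~np.isfinite(pupil) | (pupil < mu - BLINK_LOW_SD * sd) | (
            pupil > mu + BLINK_HIGH_SD * sd
        )
        spans[side] = _spans_from_mask(bad)
    return spans


def _interp_gaps(x: np.ndarray, invalid: np.ndarray) -> np.ndarray:
    """Linear interpolation over invalid samples; edge gaps take the nearest
    valid value.  Raises if nothing is valid."""
    valid = ~invalid & np.isfinite(x)
    if not valid.any():
        raise ValueError("entire channel invalid: trial unrecoverable")
    out = x.astype(float).copy()
    idx = np.arange(len(x))
    out[~valid] = np.interp(idx[~valid], idx[valid], x[valid])
    return out


def hanning_kernel(n: int = HANNING_SAMPLES) -> np.ndarray:
    k = np.hanning(n)
    return k / k.sum()


def _smooth(x: np.ndarray, n: int = HANNING_SAMPLES) -> np.ndarray:
    """Stride-1 Hanning smoothing with reflected edges (DC preserving)."""
    half = n // 2
    padded = np.concatenate([x[half:0:-1], x, x[-2 : -half - 2 : -1]])
    return np.convolve(padded, hanning_kernel(n), mode="valid")


def clean_and_smooth(
    trace: EyeTrace,
    blink_spans: dict[str, list[tuple[int, int]]],
    screen: tuple[float, float] = (1920.0, 1080.0),
    smooth: bool = True,
) -> EyeTrace:
    """Invalidate out-of-bounds samples, interpolate blink/invalid gaps per
    eye, and smooth x and y with the 15-sample Hanning window."""
    w, h = screen
    out = {}
    for side in ("left", "right"):
        x, y, pupil = (np.asarray(a, float).copy() for a in trace.eye(side))
        invalid = np.zeros(len(x), bool)
        for a, b in blink_spans.get(side, []):
            invalid[a:b] = True
        oob = (
            ~np.isfinite(x) | ~np.isfinite(y)
            | (x < 0) | (x >= w) | (y < 0) | (y >= h)
        )
        invalid |= oob
        x = _interp_gaps(x, invalid)
        y = _interp_gaps(y, invalid)
        if smooth:
            x = _smooth(x)
            y = _smooth(y)
        out[side] = (x, y, pupil, invalid)
    return EyeTrace(
        t=trace.t,
        x_left=out["left"][0],
        y_left=out["left"][1],
        pupil_left=out["left"][2],
        x_right=out["right"][0],
        y_right=out["right"][1],
        pupil_right=out["right"][2],
        interpolated_left=out["left"][3],
        interpolated_right=out["right"][3],
    )


def merge_and_downsample(
    trace: EyeTrace,
    n_frames: int,
    fps: float = 60.0,
) -> FrameGaze:
    """Merge the two eyes and bin samples to stimulus frames.

    Per sample the merged gaze is the mean of both eyes, unless one eye's
    interpolated fraction exceeds SINGLE_EYE_BAD_FRAC while the other's is
    below SINGLE_EYE_GOOD_FRAC, in which case the clean eye is used for the
    whole trial.  Samples are assigned to frame floor(t * fps) and averaged
    within frames; frames without samples are invalid.
    """
    il = (
        trace.interpolated_left
        if trace.interpolated_left is not None
        else np.zeros(trace.n_samples, bool)
    )
    ir = (
        trace.interpolated_right
        if trace.interpolated_right is not None
        else np.zeros(trace.n_samples, bool)
    )
    fl, fr = float(il.mean()), float(ir.mean())
    substituted = None
    if fl > SINGLE_EYE_BAD_FRAC and fr < SINGLE_EYE_GOOD_FRAC:
        substituted = "right"
    elif fr > SINGLE_EYE_BAD_FRAC and fl < SINGLE_EYE_GOOD_FRAC:
        substituted = "left"

    if substituted is not None:
        x, y, _ = trace.eye(substituted)
        mx, my = np.asarray(x, float), np.asarray(y, float)
    else:
        mx = (np.asarray(trace.x_left, float) + np.asarray(trace.x_right, float)) / 2
        my = (np.asarray(trace.y_left, float) + np.asarray(trace.y_right, float)) / 2

    frame_idx = np.floor(trace.t * fps).astype(int)
    keep = (frame_idx >= 0) & (frame_idx < n_frames) & np.isfinite(mx) & np.isfinite(my)
    gx = np.full(n_frames, np.nan)
    gy = np.full(n_frames, np.nan)
    counts = np.bincount(frame_idx[keep], minlength=n_frames)
    valid = counts > 0
    with np.errstate(invalid="ignore"):
        gx[valid] = (
            np.bincount(frame_idx[keep], weights=mx[keep], minlength=n_frames)[valid]
            / counts[valid]
        )
        gy[valid] = (
            np.bincount(frame_idx[keep], weights=my[keep], minlength=n_frames)[valid]
            / counts[valid]
        )
    return FrameGaze(
        gaze_x=gx,
        gaze_y=gy,
        valid=valid,
        frac_interp_left=fl,
        frac_interp_right=fr,
        substituted_eye=substituted,
    )


def flag_poor_trials(
    interp_fracs: np.ndarray,
    recorded_lengths_s: np.ndarray,
    interp_threshold: float = POOR_TRIAL_INTERP_FRAC,
) -> np.ndarray:
    """Exclusion flags over a participant's trials.

    ``interp_fracs`` is (n_trials, 2) — interpolated sample fraction per eye.
    A trial is flagged when the fraction strictly exceeds ``interp_threshold``
    in BOTH eyes, or when its recorded length lies strictly outside the
    participant's mean +/- 2 SD of trial lengths.  With fewer than 3 trials
    the length criterion is skipped with a warning.
    """
    interp_fracs = np.atleast_2d(np.asarray(interp_fracs, float))
    lengths = np.asarray(recorded_lengths_s, float)
    n = interp_fracs.shape[0]
    if lengths.shape[0] != n:
        raise ValueError("interp_fracs and recorded_lengths_s disagree on n_trials")
    flags = np.all(interp_fracs > interp_threshold, axis=1)
    if n >= 3:
        mu, sd = lengths.mean(), lengths.std()
        flags |= np.abs(lengths - mu) > 2 * sd
    else:
        warnings.warn("fewer than 3 trials: length-based exclusion skipped")
    return flags
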