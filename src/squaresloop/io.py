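"""Formats, configuration and the end-to-end pipeline.

Trial logs are exchanged as tidy tables: one row per frame per square
(``frames``) plus one row per trial of metadata (``trials``).  Two dialects
are supported — CSV (text, the deliverable format) and Parquet (columnar,
bit-equivalent after canonicalisation).  ``run_pipeline`` chains
simulate -> preprocess -> behaviour -> gaze/PE -> stats with a manifest and
content-hash caching.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import agent as agent_mod
from . import behaviour as beh_mod
from . import gaze as gaze_mod
from . import preprocess as pre_mod
from . import stats as stats_mod
from .task import (
    TaskConfig,
    TrialLog,
    VolatilitySchedule,
    build_experiment_schedule,
    simulate_trial,
)

SCHEMA_VERSION = 1

FRAME_COLUMNS = [
    "participant", "block", "trial", "frame", "square", "x", "y",
    "mouse_dx", "mouse_dy", "jitter_state", "offset_deg", "is_target",
    "is_no_control",
]

__all__ = [
    "RunConfig",
    "trial_logs_to_tables",
    "tables_to_trial_logs",
    "write_trial_logs",
    "read_trial_logs",
    "trial_logs_equal",
    "run_pipeline",
]


@dataclass
class RunConfig:
    """Every tunable of the pipeline, with the defaults used throughout."""

    n_participants: int = 4
    blocks_per_condition: int = 2
    trials_per_block: int = 18
    no_control_per_block: int = 2
    seed: int = 0
    out_dir: str = "out"
    # task
    fps: float = 60.0
    frames_per_trial: int = 900
    offset_transition_frames: int = 30
    # agent
    profile: agent_mod.AgentProfile = field(default_factory=agent_mod.AgentProfile)
    native_eye_rate_hz: float = 1000.0
    # preprocess
    poor_trial_interp_frac: float = pre_mod.POOR_TRIAL_INTERP_FRAC
    # analysis
    stickiness_beta: float = gaze_mod.STICKINESS_BETA
    moving_eps: float = beh_mod.MOVING_EPS
    pe_cumulative: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        profile = agent_mod.AgentProfile(**raw.pop("profile", {}))
        return cls(profile=profile, **raw)


# ---------------------------------------------------------------------------
# trial-log round trip


def trial_logs_to_tables(trials: list[TrialLog]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Long frames table plus trial-metadata table for a set of trials."""
    frame_rows = []
    meta_rows = []
    for tl in trials:
        F, n = tl.n_frames, tl.cfg.n_squares
        part = -1 if tl.participant is None else tl.participant
        block = -1 if tl.block is None else tl.block
        frames = np.repeat(np.arange(F), n)
        squares = np.tile(np.arange(n), F)
        df = pd.DataFrame(
            {
                "participant": part,
                "block": block,
                "trial": tl.trial_id,
                "frame": frames,
                "square": squares,
                "x": tl.square_xy[:, :, 0].ravel(),
                "y": tl.square_xy[:, :, 1].ravel(),
                "mouse_dx": np.repeat(tl.mouse_dxy[:, 0], n),
                "mouse_dy": np.repeat(tl.mouse_dxy[:, 1], n),
                "jitter_state": np.repeat(tl.jitter_state, n),
                "offset_deg": tl.offset_deg.ravel(),
                "is_target": squares == (-1 if tl.target_index is None else tl.target_index),
                "is_no_control": tl.is_no_control,
            }
        )
        frame_rows.append(df)
        meta = {
            "schema_version": SCHEMA_VERSION,
            "participant": part,
            "block": block,
            "trial": tl.trial_id,
            "variability": tl.cfg.variability_level,
            "volatility": tl.cfg.volatility_level,
            "is_no_control": tl.is_no_control,
            "target_index": -1 if tl.target_index is None else tl.target_index,
            "rng_seed": tl.rng_seed,
            "ci_narrow_deg": tl.ci_narrow_deg,
            "ci_wide_deg": tl.ci_wide_deg,
            "fps": tl.cfg.fps,
            "screen_w": tl.cfg.screen_w,
            "screen_h": tl.cfg.screen_h,
            "n_squares": n,
            "frames_per_trial": F,
        }
        for s in range(n):
            meta[f"init_x{s}"] = tl.initial_xy[s, 0]
            meta[f"init_y{s}"] = tl.initial_xy[s, 1]
        meta_rows.append(meta)
    return pd.concat(frame_rows, ignore_index=True), pd.DataFrame(meta_rows)


def tables_to_trial_logs(frames: pd.DataFrame, meta: pd.DataFrame) -> list[TrialLog]:
    missing = set(FRAME_COLUMNS) - set(frames.columns)
    if missing:
        raise ValueError(f"frames table missing columns: {sorted(missing)}")
    out = []
    key_cols = ["participant", "block", "trial"]
    frames = frames.sort_values(key_cols + ["frame", "square"], kind="stable")
    grouped = dict(tuple(frames.groupby(key_cols, sort=True)))
    for _, m in meta.sort_values(key_cols).iterrows():
        key = (int(m.participant), int(m.block), int(m.trial))
        g = grouped[key]
        F, n = int(m.frames_per_trial), int(m.n_squares)
        cfg = TaskConfig(
            frames_per_trial=F,
            fps=float(m.fps),
            n_squares=n,
            screen_w=float(m.screen_w),
            screen_h=float(m.screen_h),
            variability_level=str(m.variability),
            volatility_level=str(m.volatility),
        )
        xy = np.stack(
            [g["x"].to_numpy().reshape(F, n), g["y"].to_numpy().reshape(F, n)], axis=-1
        )
        mouse = np.stack(
            [
                g["mouse_dx"].to_numpy().reshape(F, n)[:, 0],
                g["mouse_dy"].to_numpy().reshape(F, n)[:, 0],
            ],
            axis=-1,
        )
        states = g["jitter_state"].to_numpy().reshape(F, n)[:, 0].astype(str)
        change = np.flatnonzero(states[1:] != states[:-1]) + 1
        schedule = VolatilitySchedule(
            change_frames=change, state_per_frame=states, start_state=str(states[0])
        )
        target = None if int(m.target_index) < 0 else int(m.target_index)
        init = np.stack(
            [
                np.array([m[f"init_x{s}"] for s in range(n)], float),
                np.array([m[f"init_y{s}"] for s in range(n)], float),
            ],
            axis=-1,
        )
        out.append(
            TrialLog(
                trial_id=int(m.trial),
                cfg=cfg,
                is_no_control=bool(m.is_no_control),
                target_index=target,
                rng_seed=int(m.rng_seed),
                mouse_dxy=mouse,
                square_xy=xy,
                initial_xy=init,
                jitter_state=states,
                offset_deg=g["offset_deg"].to_numpy().reshape(F, n),
                schedule=schedule,
                participant=None if int(m.participant) < 0 else int(m.participant),
                block=None if int(m.block) < 0 else int(m.block),
            )
        )
    return out


def write_trial_logs(trials: list[TrialLog], path: str | Path, dialect: str = "csv") -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    frames, meta = trial_logs_to_tables(trials)
    if dialect == "csv":
        frames.to_csv(path / "frames.csv", index=False)
        meta.to_csv(path / "trials.csv", index=False)
    elif dialect == "parquet":
        frames.to_parquet(path / "frames.parquet", index=False)
        meta.to_parquet(path / "trials.parquet", index=False)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_trial_logs(path: str | Path, dialect: str = "csv") -> list[TrialLog]:
    path = Path(path)
    if dialect == "csv":
        frames = pd.read_csv(path / "frames.csv")
        meta = pd.read_csv(path / "trials.csv")
    elif dialect == "parquet":
        frames = pd.read_parquet(path / "frames.parquet")
        meta = pd.read_parquet(path / "trials.parquet")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return tables_to_trial_logs(frames, meta)


def trial_logs_equal(a: TrialLog, b: TrialLog, atol: float = 0.0) -> bool:
    """Field-by-field equality of the persisted parts of two trial logs."""
    same = (
        a.trial_id == b.trial_id
        and a.is_no_control == b.is_no_control
        and a.target_index == b.target_index
        and a.rng_seed == b.rng_seed
        and a.cfg.condition == b.cfg.condition
        and np.allclose(a.mouse_dxy, b.mouse_dxy, atol=atol, rtol=0)
        and np.allclose(a.square_xy, b.square_xy, atol=atol, rtol=0)
        and np.allclose(a.initial_xy, b.initial_xy, atol=atol, rtol=0)
        and np.array_equal(a.jitter_state, b.jitter_state)
        and np.allclose(a.offset_deg, b.offset_deg, atol=atol, rtol=0, equal_nan=True)
    )
    return bool(same)


# ---------------------------------------------------------------------------
# pipeline


def _participant_seed(master_seed: int, participant: int, *key: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(master_seed, spawn_key=(participant, *key))


def simulate_session(cfg: RunConfig, participant: int):
    """Simulate one participant's full session (stimuli + agent + raw eyes).

    Returns ``(profile, trial_logs, agent_results, eye_traces)``.
    """
    base_rng = np.random.default_rng(_participant_seed(cfg.seed, participant, 0))
    aq = agent_mod.sample_aq(base_rng)
    profile = agent_mod.AgentProfile(
        **{**asdict(cfg.profile), "aq_score": aq}
    )
    plan = build_experiment_schedule(
        _participant_seed(cfg.seed, participant, 1),
        cfg.blocks_per_condition,
        cfg.trials_per_block,
        cfg.no_control_per_block,
    )
    task0 = TaskConfig(
        frames_per_trial=cfg.frames_per_trial,
        fps=cfg.fps,
        offset_transition_frames=cfg.offset_transition_frames,
    )
    logs, agents, eyes = [], [], []
    for k, tp in enumerate(plan):
        task = task0.with_condition(tp.variability, tp.volatility)
        ss = _participant_seed(cfg.seed, participant, 2, tp.block, tp.trial)
        s_mouse, s_trial, s_agent, s_eye = ss.spawn(4)
        mouse, _truth = agent_mod.generate_mouse_trace(profile, task, s_mouse)
        tl = simulate_trial(
            task, mouse, tp.is_no_control, s_trial,
            trial_id=k, participant=participant, block=tp.block,
        )
        res = agent_mod.simulate_gaze_agent(tl, profile, s_agent)
        eye, _info = agent_mod.inject_eye_noise(
            res.gaze_xy, profile, s_eye,
            native_rate=cfg.native_eye_rate_hz, fps=cfg.fps,
            screen=(task.screen_w, task.screen_h),
        )
        logs.append(tl)
        agents.append(res)
        eyes.append(eye)
    return profile, logs, agents, eyes


def preprocess_session(cfg: RunConfig, logs, eyes):
    """Clean and frame-align a session's eye traces; flag poor trials."""
    stats = pre_mod.pupil_stats(
        [np.concatenate([e.pupil_left, e.pupil_right]) for e in eyes]
    )
    frame_gazes, interp_fracs, lengths = [], [], []
    for tl, eye in zip(logs, eyes):
        spans = pre_mod.detect_blinks(eye, stats)
        cleaned = pre_mod.clean_and_smooth(
            eye, spans, screen=(tl.cfg.screen_w, tl.cfg.screen_h)
        )
        fg = pre_mod.merge_and_downsample(cleaned, tl.n_frames, tl.cfg.fps)
        frame_gazes.append(fg)
        interp_fracs.append([fg.frac_interp_left, fg.frac_interp_right])
        lengths.append(eye.t[-1] - eye.t[0])
    poor = pre_mod.flag_poor_trials(
        np.array(interp_fracs), np.array(lengths), cfg.poor_trial_interp_frac
    )
    return frame_gazes, poor


def analyse_session(cfg: RunConfig, participant, profile, logs, agents, frame_gazes, poor):
    """Behaviour + gaze/PE analysis for one participant's retained trials.

    Returns ``(trial_rows, pe_long, erpe_rows)``.
    """
    keep = [i for i in range(len(logs)) if not poor[i]]
    trial_events = []
    behaviours = {}
    for i in keep:
        tb = beh_mod.analyse_trial(logs[i].mouse_dxy, cfg.moving_eps, cfg.fps)
        behaviours[i] = tb
        trial_events.append(tb.turns)
    try:
        dominant, dom_counts, _tot = beh_mod.dominant_policy_stats(trial_events)
    except ValueError:
        dominant, dom_counts = None, [0] * len(keep)

    trial_rows, pe_frames, erpe_rows = [], [], []
    for j, i in enumerate(keep):
        tl, res, fg = logs[i], agents[i], frame_gazes[i]
        looked = gaze_mod.assign_hypotheses(
            fg.gaze_x, fg.gaze_y, tl.square_xy, cfg.stickiness_beta,
            (tl.cfg.screen_w, tl.cfg.screen_h),
        )
        switches, deflick = gaze_mod.detect_hypothesis_switches(looked)
        series = gaze_mod.prediction_error_series(tl, deflick, cumulative=cfg.pe_cumulative)
        correct = (
            res.response == 0 if tl.is_no_control
            else (res.response - 1) == tl.target_index
        )
        tb = behaviours[i]
        trial_rows.append(
            {
                "participant": participant,
                "block": tl.block,
                "trial": tl.trial_id,
                "variability": tl.cfg.variability_level,
                "volatility": tl.cfg.volatility_level,
                "is_no_control": tl.is_no_control,
                "aq": profile.aq_score,
                "response": res.response,
                "accuracy": int(correct),
                "judged_agency": int(res.response != 0),
                "time_moving": tb.time_moving_s,
                "time_to_onset": tb.time_to_movement_onset_s,
                "speed": tb.mean_speed_px_per_frame,
                "accel": tb.mean_accel,
                "jerk": tb.mean_jerk,
                "n_turns": tb.n_turns,
                "dominant_turns": dom_counts[j],
                "dominant_policy": dominant,
                "n_switches": int(len(switches)),
                "mean_pe": series.trial_mean,
                # simulation ground truth, kept for parameter-recovery checks
                "mean_abs_jitter_deg": (
                    float(np.mean(np.abs(tl.jitter_deg)))
                    if tl.jitter_deg is not None
                    else np.nan
                ),
            }
        )
        F = tl.n_frames
        pe_frames.append(
            pd.DataFrame(
                {
                    "participant": participant,
                    "trial": tl.trial_id,
                    "frame": np.arange(F),
                    "pe_px": series.pe_px,
                    "looked_square": deflick,
                    "variability": tl.cfg.variability_level,
                    "volatility": tl.cfg.volatility_level,
                    "accuracy": int(correct),
                    "judged_agency": int(res.response != 0),
                }
            )
        )
        for event_type, evs in (
            ("hypothesis_switch", switches),
            ("volatility_change", tl.schedule.change_frames),
        ):
            _, bin_means = gaze_mod.erpe_epochs(series.pe_px, evs)
            for e_idx in range(bin_means.shape[0]):
                for b in range(bin_means.shape[1]):
                    erpe_rows.append(
                        {
                            "participant": participant,
                            "trial": tl.trial_id,
                            "variability": tl.cfg.variability_level,
                            "volatility": tl.cfg.volatility_level,
                            "event_type": event_type,
                            "epoch": e_idx,
                            "time_bin": b + 1,
                            "bin_pe": bin_means[e_idx, b],
                        }
                    )
    pe_long = (
        pd.concat(pe_frames, ignore_index=True)
        if pe_frames
        else pd.DataFrame(
            columns=["participant", "trial", "frame", "pe_px", "looked_square",
                     "variability", "volatility", "accuracy", "judged_agency"]
        )
    )
    return pd.DataFrame(trial_rows), pe_long, pd.DataFrame(erpe_rows)


def _hash_obj(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def run_pipeline(cfg: RunConfig, fit_models: bool = True, log=print) -> dict:
    """End-to-end run: simulate every participant, preprocess, analyse and
    (optionally) fit the confirmatory models.  Writes tables and a manifest
    to ``cfg.out_dir``; unchanged stages (same config hash) are loaded from
    their cached outputs rather than recomputed.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = _hash_obj(asdict(cfg))
    manifest_path = out / "manifest.json"
    manifest = {"schema_version": SCHEMA_VERSION, "config_hash": cfg_hash,
                "config": asdict(cfg), "stages": {}, "outputs": {}}
    old = {}
    if manifest_path.exists():
        try:
            old = json.loads(manifest_path.read_text())
        except json.JSONDecodeError:
            old = {}

    stage_files = {
        "analyse": ["trial_table.csv", "pe_long.csv", "erpe.csv", "participants.csv"],
    }
    cached = (
        old.get("config_hash") == cfg_hash
        and all((out / f).exists() for f in stage_files["analyse"])
    )
    t0 = time.time()
    if cached:
        log("pipeline: outputs up to date, loading cached tables")
        trial_table = pd.read_csv(out / "trial_table.csv")
        pe_long = pd.read_csv(out / "pe_long.csv")
        erpe = pd.read_csv(out / "erpe.csv")
        participants = pd.read_csv(out / "participants.csv")
    else:
        trial_tabs, pe_tabs, erpe_tabs, part_rows = [], [], [], []
        for p in range(cfg.n_participants):
            log(f"pipeline: participant {p}: simulate")
            profile, logs, agents, eyes = simulate_session(cfg, p)
            log(f"pipeline: participant {p}: preprocess")
            frame_gazes, poor = preprocess_session(cfg, logs, eyes)
            log(f"pipeline: participant {p}: analyse ({int(poor.sum())} poor trials)")
            tt, pl, er = analyse_session(cfg, p, profile, logs, agents, frame_gazes, poor)
            trial_tabs.append(tt)
            pe_tabs.append(pl)
            erpe_tabs.append(er)
            part_rows.append({"participant": p, "aq_score": profile.aq_score,
                              "n_poor_trials": int(poor.sum())})
        trial_table = pd.concat(trial_tabs, ignore_index=True)
        pe_long = pd.concat(pe_tabs, ignore_index=True)
        erpe = pd.concat(erpe_tabs, ignore_index=True)
        participants = pd.DataFrame(part_rows)
        trial_table.to_csv(out / "trial_table.csv", index=False)
        pe_long.to_csv(out / "pe_long.csv", index=False)
        erpe.to_csv(out / "erpe.csv", index=False)
        participants.to_csv(out / "participants.csv", index=False)

    tables = stats_mod.build_tables(trial_table, pe_long, fps=cfg.fps)
    results = {"tables": {**tables, "erpe": erpe, "participants": participants}}

    if fit_models and trial_table["participant"].nunique() >= 2:
        log("pipeline: fitting mixed models")
        specs = stats_mod.confirmatory_model_specs()
        fits = {}
        for name in ("accuracy", "time_moving", "speed", "n_switches", "mean_pe"):
            try:
                fits[name] = stats_mod.fit_mixed_model(specs[name], tables["trial"])
            except (ValueError, KeyError) as exc:
                log(f"pipeline: model {name} skipped ({exc})")
        if "condition_slopes" in tables and len(tables["condition_slopes"]):
            slopes = tables["condition_slopes"].rename(columns={"slope": "slope"})
            try:
                fits["condition_slope"] = stats_mod.fit_mixed_model(
                    stats_mod.ModelSpec("slope", ("variability * volatility * aq",),
                                        data_grain="condition"),
                    slopes,
                )
            except ValueError as exc:
                log(f"pipeline: model condition_slope skipped ({exc})")
        results["fits"] = fits
        effects = pd.concat(
            [f.effects.assign(model=k) for k, f in fits.items()], ignore_index=True
        ) if fits else pd.DataFrame()
        effects.to_csv(out / "effects.csv", index=False)

    for f in out.glob("*.csv"):
        manifest["outputs"][f.name] = _hash_file(f)
    manifest["stages"]["pipeline"] = {"seconds": round(time.time() - t0, 2),
                                      "cached": bool(cached)}
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    results["manifest"] = manifest
    return results
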