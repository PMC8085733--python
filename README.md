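# squaresloop

A closed-loop simulator and analysis pipeline for a multi-square
judgement-of-agency task, with synthetic participants so every analysis
stage is testable without human data.

Eight squares move whenever the mouse moves: one (the target) follows the
mouse direction up to angular jitter; the other seven add a per-distractor
angular offset that is redrawn five times per trial. The width of the jitter
distribution (*variability*: 10°↔30° or 90°↔110° 95% CI) alternates within
each 15 s trial on a pseudo-random schedule (*volatility*: 3 or 10 changes,
≥ 50 frames apart). At the end of each trial a (synthetic) participant names
the square they controlled, or 0 for none.

The pipeline then mirrors the full analysis chain:

| stage | module | what it does |
| --- | --- | --- |
| stimulus engine | `squaresloop.task` | volatility schedules, jitter, distractor offsets, trial simulation, block/trial plans |
| synthetic participants | `squaresloop.agent` | policy-driven mouse traces, a threshold-switching gaze agent, eye-tracker artifact injection, agency judgements |
| eye preprocessing | `squaresloop.preprocess` | pupil-based blink spans, interpolation, 15-sample Hanning smoothing, binocular merging, frame alignment, poor-trial flags |
| behaviour | `squaresloop.behaviour` | speed/acceleration/jerk, time moving, 8-direction discretisation, turn detection, six-policy classification, dominant policy, motor-control index |
| gaze / prediction error | `squaresloop.gaze` | biased-nearest-object assignment, hypothesis switches, one-step prediction-error proxy, PE slopes, event-related PE (five 200 ms bins) |
| statistics | `squaresloop.stats` | trial-/condition-wise tables, REML mixed models with by-participant intercepts, Bonferroni post-hocs with AQ-group probing |
| I/O + pipeline | `squaresloop.io`, `squaresloop.cli` | CSV/Parquet trial-log round-trip, run config, manifest + cached end-to-end runs |

## CLI

```sh
# stimulus logs only (CSV tables: frames.csv + trials.csv)
squares-loop simulate --participants 2 --seed 1 --out out/sim

# synthetic-participant fixtures: trial logs, raw 1000 Hz eye CSVs,
# ground-truth annotations, participants table
squares-loop synthesize --n 40 --seed 1 --out out/syn

# clean raw eye data against its trial logs
squares-loop preprocess --in out/syn/participant_000 \
    --trials out/syn/participant_000 --out out/clean

# full pipeline (simulate -> preprocess -> behaviour -> PE -> models)
squares-loop run-all --participants 4 --seed 1 --out out/run

# refit the confirmatory models on written tables
squares-loop report --tables out/run --out out/report
```

`run-all` writes `trial_table.csv`, `pe_long.csv`, `erpe.csv`,
`participants.csv`, `effects.csv` and a `manifest.json` recording the config
hash and per-output content hashes; re-running with an unchanged config
loads the cached tables. A YAML config (`--config`) can override any
`RunConfig` field, including agent-profile parameters.

## Notes

- Coordinates are y-down screen pixels; angles clockwise-positive from +x;
  the screen wraps toroidally and all distances are minimum-image.
- The prediction-error proxy is one-step-ahead (expected position =
  previous actual position + current mouse displacement); a cumulative
  variant is available via `prediction_error_series(..., cumulative=True)`.
- Synthetic agents are sign-level stand-ins: they reproduce effect
  directions (e.g. wide jitter lowers judgement accuracy, prediction error
  peaks at hypothesis switches), not human effect magnitudes.
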