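import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from squaresloop.task import (
    Z95,
    TaskConfig,
    build_experiment_schedule,
    make_distractor_offsets,
    make_volatility_schedule,
    sample_jitter_angle,
    simulate_trial,
    step_squares,
    wrap_delta,
    wrap_distance,
)


class TestTaskConfig:
    def test_defaults(self, cfg):
        assert cfg.frames_per_trial == 900
        assert cfg.fps == 60
        assert cfg.n_squares == 8
        assert cfg.ci_pair_deg == (10.0, 30.0)
        assert cfg.n_volatility_changes == 3
        assert cfg.trial_seconds == 15.0

    def test_condition_mapping(self):
        assert TaskConfig(variability_level="high").ci_pair_deg == (90.0, 110.0)
        assert TaskConfig(volatility_level="high").n_volatility_changes == 10

    def test_invalid_ci(self):
        with pytest.raises(ValueError):
            TaskConfig(ci_pair_deg=(30.0, 10.0))
        with pytest.raises(ValueError):
            TaskConfig(ci_pair_deg=(0.0, 10.0))

    def test_infeasible_schedule(self):
        with pytest.raises(ValueError):
            TaskConfig(n_volatility_changes=20, min_change_gap_frames=50)

    def test_frame_count_tied_to_fps(self):
        with pytest.raises(ValueError):
            TaskConfig(frames_per_trial=800)


class TestVolatilitySchedule:
    def test_low_three_changes(self, cfg):
        assert make_volatility_schedule(cfg, 0).n_changes == 3

    def test_high_ten_changes_min_gap(self, cfg_high):
        sch = make_volatility_schedule(cfg_high, 0)
        assert sch.n_changes == 10
        assert np.diff(sch.change_frames).min() >= 50

    def test_zero_changes_constant(self):
        cfg = TaskConfig(n_volatility_changes=0)
        sch = make_volatility_schedule(cfg, 5)
        assert sch.change_frames.size == 0
        assert len(set(sch.state_per_frame)) == 1

    def test_alternation_and_start_state(self, cfg):
        sch = make_volatility_schedule(cfg, 3)
        assert sch.state_per_frame[0] == sch.start_state
        for f in sch.change_frames:
            assert sch.state_per_frame[f] != sch.state_per_frame[f - 1]

    def test_deterministic(self, cfg_high):
        a = make_volatility_schedule(cfg_high, 17)
        b = make_volatility_schedule(cfg_high, 17)
        assert np.array_equal(a.change_frames, b.change_frames)
        assert a.start_state == b.start_state

    @pytest.mark.parametrize("volatility", ["low", "high"])
    def test_many_seeds_respect_gap(self, volatility):
        cfg = TaskConfig(volatility_level=volatility)
        for seed in range(200):
            sch = make_volatility_schedule(cfg, seed)
            assert sch.n_changes == cfg.n_volatility_changes
            if sch.n_changes > 1:
                assert np.diff(sch.change_frames).min() >= 50
            assert sch.change_frames.min() >= 50


class TestJitter:
    def test_ci10_empirical_halfwidth(self, rng):
        draws = sample_jitter_angle(10.0, rng, size=100_000)
        lo, hi = np.percentile(draws, [2.5, 97.5])
        assert (hi - lo) / 2 == pytest.approx(10.0, abs=0.3)

    def test_tiny_ci_limit(self, rng):
        draws = sample_jitter_angle(1e-9, rng, size=1000)
        assert np.abs(draws).max() < 1e-8

    def test_ci90_sd(self, rng):
        draws = sample_jitter_angle(90.0, rng, size=100_000)
        assert draws.std() == pytest.approx(90.0 / Z95, abs=0.35)
        assert 90.0 / Z95 == pytest.approx(45.92, abs=0.01)

    def test_nonpositive_ci_rejected(self, rng):
        with pytest.raises(ValueError):
            sample_jitter_angle(0.0, rng)
        with pytest.raises(ValueError):
            sample_jitter_angle(-5.0, rng)


class TestDistractorOffsets:
    def test_five_redraw_onsets(self, cfg):
        offsets, onsets = make_distractor_offsets(cfg, 7, 0)
        assert offsets.shape == (900, 7)
        for frames in onsets:
            assert len(frames) == 5

    def test_zero_transition_steps(self):
        cfg = TaskConfig(offset_transition_frames=0)
        offsets, onsets = make_distractor_offsets(cfg, 1, 2)
        # piecewise constant with exactly 5 discontinuities
        jumps = np.flatnonzero(np.diff(offsets[:, 0]) != 0) + 1
        assert np.array_equal(np.sort(jumps), np.sort(onsets[0]))

    def test_shortest_arc_transitions(self, cfg):
        # during each ramp the per-frame deltas share one sign and total to
        # the shortest-arc difference (never > 180 deg of total travel)
        offsets, onsets = make_distractor_offsets(cfg, 4, 7)
        T = cfg.offset_transition_frames
        for d in range(4):
            x = offsets[:, d]
            for f in onsets[d]:
                seg = x[f - 1 : f + T]
                step = (np.diff(seg) + 180.0) % 360.0 - 180.0
                assert np.all(step >= -1e-9) or np.all(step <= 1e-9)
                total = step.sum()
                assert abs(total) <= 180.0 + 1e-9

    def test_wrap_through_zero(self):
        from squaresloop.task import _shortest_arc_delta

        assert _shortest_arc_delta(350.0, 10.0) == pytest.approx(20.0)
        assert _shortest_arc_delta(10.0, 350.0) == pytest.approx(-20.0)

    def test_independent_across_distractors(self, cfg):
        offsets, _ = make_distractor_offsets(cfg, 7, 9)
        assert np.std(offsets[0, :]) > 0  # initial offsets differ


class TestStepSquares:
    def test_identity_noise_free(self):
        pos = np.array([[100.0, 100.0]])
        out = step_squares(pos, 10.0, 0.0, np.zeros(1), np.zeros(1))
        assert np.allclose(out, [[110.0, 100.0]])

    def test_offset_rotation_y_down(self):
        pos = np.array([[100.0, 100.0]])
        out = step_squares(pos, 10.0, 0.0, np.zeros(1), np.array([90.0]))
        assert np.allclose(out, [[100.0, 110.0]], atol=1e-9)

    def test_stationary_mouse(self, rng):
        pos = rng.uniform(0, 1000, size=(8, 2))
        out = step_squares(pos, 0.0, 0.0, rng.normal(size=8), rng.uniform(0, 360, 8))
        assert np.array_equal(out, pos)

    @given(
        dx=st.floats(-20, 20), dy=st.floats(-20, 20),
        seed=st.integers(0, 10_000),
    )
    @settings(max_examples=50, deadline=None)
    def test_magnitude_conserved(self, dx, dy, seed):
        r = np.random.default_rng(seed)
        pos = r.uniform(0, [1920, 1080], size=(8, 2))
        out = step_squares(pos, dx, dy, r.normal(0, 50, 8), r.uniform(0, 360, 8))
        moved = wrap_distance(out, pos, np.array([1920.0, 1080.0]))
        assert np.allclose(moved, np.hypot(dx, dy), atol=1e-8)


@pytest.fixture(scope="module")
def mouse():
    r = np.random.default_rng(0)
    m = r.normal(0, 4, size=(900, 2))
    m[100:130] = 0.0  # a pause
    return m


class TestSimulateTrial:
    def test_agentive_single_offset_free_square(self, cfg, mouse):
        tl = simulate_trial(cfg, mouse, False, 11)
        assert tl.target_index is not None
        nan_cols = np.isnan(tl.offset_deg).all(axis=0)
        assert nan_cols.sum() == 1 and nan_cols[tl.target_index]

    def test_no_control_all_offset_bearing(self, cfg, mouse):
        tl = simulate_trial(cfg, mouse, True, 11)
        assert tl.target_index is None
        assert tl.is_no_control
        assert not np.isnan(tl.offset_deg).any()

    def test_deterministic(self, cfg, mouse):
        a = simulate_trial(cfg, mouse, False, 42)
        b = simulate_trial(cfg, mouse, False, 42)
        assert np.array_equal(a.square_xy, b.square_xy)
        assert a.target_index == b.target_index

    def test_positions_in_bounds(self, cfg, mouse):
        tl = simulate_trial(cfg, mouse, False, 13)
        assert tl.square_xy[..., 0].min() >= 0 and tl.square_xy[..., 0].max() < 1920
        assert tl.square_xy[..., 1].min() >= 0 and tl.square_xy[..., 1].max() < 1080

    def test_stationary_frames_freeze_squares(self, cfg, mouse):
        tl = simulate_trial(cfg, mouse, False, 13)
        assert np.array_equal(tl.square_xy[100:130], np.repeat(tl.square_xy[99:100], 30, axis=0))

    def test_displacement_magnitude_equals_mouse(self, cfg, mouse):
        tl = simulate_trial(cfg, mouse, True, 5)
        period = np.array([1920.0, 1080.0])
        prev = tl.positions_before()
        moved = wrap_distance(tl.square_xy, prev, period)
        speed = np.hypot(mouse[:, 0], mouse[:, 1])
        assert np.allclose(moved, speed[:, None], atol=1e-6)

    def test_trace_length_mismatch(self, cfg):
        with pytest.raises(ValueError):
            simulate_trial(cfg, np.zeros((10, 2)), False, 0)

    def test_structural_symmetry_no_jitter_no_offset(self, cfg):
        # iterating step_squares with jitter and offsets zeroed, every square
        # traces the wrapped mouse path exactly
        r = np.random.default_rng(3)
        mouse = r.normal(0, 5, size=(200, 2))
        pos = r.uniform(0, [1920, 1080], size=(8, 2))
        path = pos.copy()
        for dx, dy in mouse:
            path = step_squares(path, dx, dy, np.zeros(8), np.zeros(8))
        integral = (pos + mouse.sum(axis=0)) % np.array([1920.0, 1080.0])
        assert np.allclose(path, integral, atol=1e-8)

    def test_vectorised_matches_step_squares(self, cfg, mouse):
        # replay the logged jitter/offsets through the scalar stepper
        tl = simulate_trial(cfg, mouse, True, 21)
        pos = tl.initial_xy.copy()
        for f in range(150):
            pos = step_squares(
                pos, mouse[f, 0], mouse[f, 1], tl.jitter_deg[f], tl.offset_deg[f]
            )
            assert np.allclose(pos, tl.square_xy[f], atol=1e-8)

    def test_jitter_wider_in_wide_state(self, cfg, mouse):
        tl = simulate_trial(cfg, mouse, False, 33)
        speed = np.hypot(mouse[:, 0], mouse[:, 1])
        narrow = (tl.jitter_state == "narrow") & (speed > 0)
        wide = (tl.jitter_state == "wide") & (speed > 0)
        assert tl.jitter_deg[narrow].std() < tl.jitter_deg[wide].std()


class TestExperimentSchedule:
    def test_counts(self):
        plan = build_experiment_schedule(0)
        assert len(plan) == 144
        assert sum(p.is_no_control for p in plan) == 16
        assert sum(not p.is_no_control for p in plan) == 128

    def test_block_sizes(self):
        plan = build_experiment_schedule(3)
        blocks = {}
        for p in plan:
            blocks.setdefault(p.block, []).append(p)
        assert len(blocks) == 8
        for trials in blocks.values():
            assert len(trials) == 18
            assert sum(t.is_no_control for t in trials) == 2
            assert len({(t.variability, t.volatility) for t in trials}) == 1

    def test_condition_conservation_across_seeds(self):
        for seed in (1, 2):
            plan = build_experiment_schedule(seed)
            conds = {}
            for p in plan:
                conds[(p.variability, p.volatility)] = conds.get((p.variability, p.volatility), 0) + 1
            assert all(v == 36 for v in conds.values())

    def test_orders_can_differ(self):
        orders = set()
        for seed in range(5):
            plan = build_experiment_schedule(seed)
            first_per_block = tuple(
                (p.variability, p.volatility) for p in plan if p.trial == 0
            )
            orders.add(first_per_block)
        assert len(orders) > 1


class TestWrap:
    def test_wrap_delta_minimum_image(self):
        period = np.array([1920.0, 1080.0])
        d = wrap_delta(np.array([10.0, 10.0]), np.array([1910.0, 1070.0]), period)
        assert np.allclose(d, [20.0, 20.0])

    def test_wrap_distance_symmetry(self, rng):
        period = np.array([1920.0, 1080.0])
        a = rng.uniform(0, period, size=(50, 2))
        b = rng.uniform(0, period, size=(50, 2))
        assert np.allclose(wrap_distance(a, b, period), wrap_distance(b, a, period))
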