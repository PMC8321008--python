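import numpy as np

from mealtrack.preprocess import ForegroundBlob
from mealtrack.session_detector import (
    HeightHistory,
    SessionConfig,
    detect_sessions,
    hands_on_table,
    is_sitting,
    near_table,
    rollover,
    run_checklist,
)
from mealtrack.synthetic_scene import render_background, render_sequence, scripted_leave_and_return
from mealtrack.types import DepthFrame

SCALE = 0.25


def _blob_at(x, y, depth=1700):
    mask = np.zeros((480, 640), dtype=bool)
    mask[y, x] = True
    values = np.full((480, 640), 3000, dtype=np.int64)
    values[y, x] = depth
    return ForegroundBlob(mask, values, (float(x), float(y)), 1, (x, y, depth))


class TestNearTable:
    cfg = SessionConfig(table_rect=(360, 140, 580, 340), dist_px=45)

    def test_head_inside_the_rect(self):
        assert near_table(_blob_at(400, 200), self.cfg)

    def test_exactly_dist_outside_is_inclusive(self):
        assert near_table(_blob_at(360 - 45, 200), self.cfg)

    def test_one_pixel_beyond_dist_is_out(self):
        assert not near_table(_blob_at(360 - 46, 200), self.cfg)


class TestIsSitting:
    cfg = SessionConfig(ratio=0.3)

    def _history(self, baseline):
        h = HeightHistory()
        h.record(baseline, sitting=False)
        return h

    def test_known_seated_reading_fires(self):
        # 1700 mm seated against a 1190 mm standing baseline: 1700*0.7 = 1190
        assert is_sitting(self._history(1190.0), 1700.0, self.cfg)

    def test_just_below_the_threshold_does_not(self):
        assert not is_sitting(self._history(1190.0), 1600.0, self.cfg)

    def test_current_equal_to_baseline_is_standing(self):
        assert not is_sitting(self._history(1200.0), 1200.0, self.cfg)

    def test_pending_baseline_is_standing(self):
        assert not is_sitting(HeightHistory(), 1700.0, self.cfg)

    def test_threshold_on_standing_dialect(self):
        cfg = SessionConfig(ratio=0.3, sitting_dialect="threshold-on-standing")
        assert is_sitting(self._history(1200.0), 1561.0, cfg)
        assert not is_sitting(self._history(1200.0), 1559.0, cfg)
        # the seated-threshold dialect needs a larger increase: 1560*0.7 < 1200
        assert not is_sitting(self._history(1200.0), 1560.0, self.cfg)

    def test_baseline_is_a_running_minimum_of_standing_frames(self):
        h = HeightHistory()
        for d, sitting in [(1250.0, False), (1190.0, False), (1700.0, True), (1180.0, False)]:
            h.record(d, sitting)
        assert h.baseline == 1180.0


def _table_scene(fg_spec, table_rect=(40, 20, 120, 80), table_top=2100):
    """Frame + foreground mask with rectangles of given depth over the table."""
    frame = np.full((120, 160), 3000, dtype=np.int64)
    x0, y0, x1, y1 = table_rect
    frame[y0:y1, x0:x1] = table_top
    fg = np.zeros((120, 160), dtype=bool)
    for (sy, sx, h, w, depth) in fg_spec:
        frame[sy : sy + h, sx : sx + w] = depth
        fg[sy : sy + h, sx : sx + w] = True
    cfg = SessionConfig(
        table_rect=table_rect, table_top_mm=table_top, hand_gap_mm=200, hand_area_px=300
    )
    return DepthFrame(frame), fg, cfg


class TestHandsOnTable:
    def test_single_hand_blob_detected(self):
        # 20x20 = 400 px at 120 mm above the table
        frame, fg, cfg = _table_scene([(30, 50, 20, 20, 2100 - 120)])
        assert len(hands_on_table(frame, fg, cfg)) == 1

    def test_protruding_trunk_fails_the_hand_gap(self):
        frame, fg, cfg = _table_scene([(30, 50, 30, 30, 2100 - 450)])
        assert hands_on_table(frame, fg, cfg) == []

    def test_two_hands_give_two_blobs(self):
        frame, fg, cfg = _table_scene(
            [(30, 45, 19, 19, 1980), (60, 45, 19, 19, 1995)]
        )
        assert len(hands_on_table(frame, fg, cfg)) == 2

    def test_area_threshold_is_strict(self):
        frame, fg, cfg = _table_scene([(30, 50, 10, 10, 1980)])  # 100 px only
        assert hands_on_table(frame, fg, cfg) == []


class TestDetectSessions:
    def test_clean_scene_recovers_the_scripted_bounds(self, mini_scene, mini_cfg):
        script, frames, truth, background = mini_scene
        table = detect_sessions(frames, background, mini_cfg, test_number=3)
        assert len(table) == 1
        seg = table.segments[0]
        assert seg.test_number == 3
        assert abs(seg.sf - truth.sf_true) <= 5
        assert abs(seg.ef - truth.ef_true) <= 5

    def test_empty_scene_yields_empty_table(self, mini_cfg):
        from mealtrack.synthetic_scene import SceneScript

        script = SceneScript(
            width=160, height=120, table_rect=mini_cfg.table_rect, n_frames=40
        )
        frames, _ = render_sequence(script)
        bg = render_background(script)
        assert len(detect_sessions(frames, bg, mini_cfg)) == 0

    def test_leave_and_return_splits_the_meal(self, mini_cfg):
        script = scripted_leave_and_return((1, 1), scale=SCALE, seed=21)
        frames, truth = render_sequence(script)
        bg = render_background(script)
        table = detect_sessions(frames, bg, mini_cfg, test_number=11)
        assert len(table) == 2
        first, second = table.segments
        assert second.sf > first.ef
        assert abs(first.sf - truth.visit_bounds[0][0]) <= 5
        assert abs(second.sf - truth.visit_bounds[1][0]) <= 5

    def test_sequence_starting_mid_meal_emits_sf_one(self, mini_scene, mini_cfg):
        script, frames, truth, background = mini_scene
        v = script.visits[0]
        mid = (v.hands_on_table + v.stand) // 2
        table = detect_sessions(frames[mid:], background, mini_cfg)
        assert len(table) == 1
        assert table.segments[0].sf == 1

    def test_lowering_the_ratio_never_delays_the_start(self, mini_scene, mini_cfg):
        from dataclasses import replace

        script, frames, truth, background = mini_scene
        sf_by_ratio = []
        # a 0.45 seated drop supports ratios up to 1 - 1/1.45 ~ 0.31
        for ratio in (0.3, 0.25, 0.2):
            cfg = replace(mini_cfg, ratio=ratio)
            table = detect_sessions(frames, background, cfg)
            assert len(table) == 1
            sf_by_ratio.append(table.segments[0].sf)
        assert sf_by_ratio == sorted(sf_by_ratio, reverse=True)

    def test_checklist_short_circuits(self, mini_scene, mini_cfg):
        script, frames, truth, background = mini_scene
        states = run_checklist(frames, background, mini_cfg)
        for st in states:
            if not st.present:
                assert st.near is None and st.sitting is None and st.hands is None
            elif st.near is False:
                assert st.sitting is None and st.hands is None
            elif st.sitting is False:
                assert st.hands is None

    def test_every_segment_lies_within_the_file(self, mini_scene, mini_cfg):
        script, frames, truth, background = mini_scene
        for seg in detect_sessions(frames, background, mini_cfg):
            assert 1 <= seg.sf <= seg.ef <= len(frames)


class TestRollover:
    def _frames(self, n):
        return [DepthFrame(np.ones((2, 2), dtype=np.int64), i) for i in range(n)]

    def test_fifteen_minutes_is_one_file(self):
        assert len(rollover(self._frames(27000))) == 1

    def test_one_extra_frame_rolls_over(self):
        chunks = rollover(self._frames(27001))
        assert [len(c) for c in chunks] == [27000, 1]

    def test_empty_input_has_no_chunks(self):
        assert rollover([]) == []

    def test_custom_chunking(self):
        chunks = rollover(self._frames(10), rollover_frames=4)
        assert [len(c) for c in chunks] == [4, 4, 2]
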