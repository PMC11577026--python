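import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from territory.arena import ArenaLayout, ROI, roi_labels
from territory.metrics import (
    DwellBout,
    compute_trajectory_metrics,
    dwell_bouts,
    exploration_time,
    hiding_time,
    min_dwell_filter,
    proximity_time,
)

from conftest import FPS, make_track, scripted_path


def labels_from_bools(values, name="roi"):
    return pd.DataFrame({name: pd.array(values, dtype="boolean")})


class TestDwellBouts:
    def test_in_in_out_in(self):
        b = dwell_bouts(labels_from_bools([True, True, False, True]), "roi", FPS)
        assert [(x.start_frame, x.end_frame) for x in b] == [(0, 2), (3, 4)]

    def test_never_inside(self):
        assert dwell_bouts(labels_from_bools([False] * 5), "roi", FPS) == []

    @given(st.lists(st.booleans(), min_size=1, max_size=200))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_matches_run_length_encoding_oracle(self, bits):
        got = dwell_bouts(labels_from_bools(bits), "roi", FPS)
        # oracle: scan run-length encoding
        runs, start = [], None
        for i, v in enumerate(bits):
            if v and start is None:
                start = i
            if not v and start is not None:
                runs.append((start, i))
                start = None
        if start is not None:
            runs.append((start, len(bits)))
        assert [(b.start_frame, b.end_frame) for b in got] == runs


class TestMinDwellFilter:
    def test_threshold_boundary(self):
        fps = 45.0
        short = DwellBout("r", 0, 22, fps)  # ~0.49 s
        exact = DwellBout("r", 30, 75, fps)  # exactly 1.0 s
        long = DwellBout("r", 100, 190, fps)  # 2.0 s
        assert min_dwell_filter([short, exact, long]) == [exact, long]
        assert min_dwell_filter([]) == []

    def test_idempotent_and_monotone(self):
        rng = np.random.default_rng(0)
        bits = rng.uniform(size=400) < 0.5
        bouts = dwell_bouts(labels_from_bools(list(bits)), "roi", FPS)
        once = min_dwell_filter(bouts, 1.0)
        assert min_dwell_filter(once, 1.0) == once
        bigger = min_dwell_filter(bouts, 2.0)
        assert set((b.start_frame, b.end_frame) for b in bigger) <= set(
            (b.start_frame, b.end_frame) for b in once
        )


class TestHidingTime:
    def test_parked_in_corner_whole_window(self, layout):
        path = scripted_path([(1200, (4.0, 4.0))])  # corner_1_tl centre
        lab = roi_labels(make_track(path), layout)
        assert hiding_time(lab, layout, (0, 1200)) == pytest.approx(1200.0)

    def test_never_hiding(self, layout):
        path = scripted_path([(60, (30.0, 30.0))])  # open floor, compartment 1
        lab = roi_labels(make_track(path), layout)
        assert hiding_time(lab, layout) == 0.0

    def test_scripted_schedule_sum(self, layout):
        # visits: corner 10 s, open 5 s, cage top 0.5 s (discarded), open 4 s,
        # food top 20 s, corner again 0.5 s (discarded) -> 30 s hiding
        segs = [
            (10, (4.0, 4.0)),        # corner_1_tl
            (5, (30.0, 30.0)),       # open floor
            (0.5, (60.0, 30.0)),     # cage_top_1 (also < 1 s)
            (4, (30.0, 40.0)),       # open floor
            (20, (60.0, 30.0)),      # cage/food centre: cage_top_1 + food_top_1
            (0.5, (4.0, 4.0)),       # corner, sub-second
            (2, (30.0, 30.0)),
        ]
        lab = roi_labels(make_track(scripted_path(segs)), layout)
        assert hiding_time(lab, layout) == pytest.approx(30.0)

    def test_window_restriction(self, layout):
        path = scripted_path([(100, (4.0, 4.0))])
        lab = roi_labels(make_track(path), layout)
        assert hiding_time(lab, layout, (0, 40)) == pytest.approx(40.0)


class TestExplorationTime:
    def test_never_leaving_own_compartment(self, layout):
        path = scripted_path([(120, (30.0, 30.0))])
        lab = roi_labels(make_track(path), layout)
        assert exploration_time(lab, layout, own_compartment_id=1) == 0.0

    def test_subtracts_hiding_in_opponent_compartment(self, layout):
        # mouse of compartment 1 spends 300 s in compartment 2,
        # 100 s of it in a compartment-2 corner -> 200 s exploration
        segs = [
            (200, (30.0, 90.0)),   # open floor of compartment 2
            (100, (4.0, 64.0)),    # corner_2_tl (hiding)
        ]
        lab = roi_labels(make_track(scripted_path(segs)), layout)
        assert exploration_time(lab, layout, 1) == pytest.approx(200.0)

    def test_scripted_crossing_schedule(self, layout):
        segs = [
            (50, (30.0, 30.0)),    # home side
            (40, (30.0, 90.0)),    # opponent open floor
            (10, (4.0, 64.0)),     # opponent corner (hiding)
            (0.5, (30.0, 90.0)),   # sub-second blip, discarded
            (30, (30.0, 30.0)),    # home again
        ]
        lab = roi_labels(make_track(scripted_path(segs)), layout)
        # contiguous compartment-2 bout: 360 + 90 + 4 frames; 90 hiding
        assert exploration_time(lab, layout, 1) == pytest.approx(364 / FPS)


class TestProximityTime:
    def test_co_parked_close(self, layout):
        a = make_track(scripted_path([(60, (30.0, 30.0))]), mouse_id="a")
        b = make_track(scripted_path([(60, (35.0, 30.0))]), mouse_id="b")
        assert proximity_time(a, b, layout) == pytest.approx(60.0)

    def test_close_but_across_divider(self, layout):
        a = make_track(scripted_path([(60, (30.0, 58.0))]), mouse_id="a")
        b = make_track(scripted_path([(60, (30.0, 62.0))]), mouse_id="b")
        assert proximity_time(a, b, layout) == 0.0

    def test_symmetric(self, layout):
        rng = np.random.default_rng(5)
        pa = np.clip(rng.normal(30, 10, (300, 2)), 2, 58)
        pb = np.clip(rng.normal(30, 10, (300, 2)), 2, 58)
        a, b = make_track(pa, mouse_id="a"), make_track(pb, mouse_id="b")
        assert proximity_time(a, b, layout) == proximity_time(b, a, layout)

    def test_matches_per_frame_oracle_without_filter(self, layout):
        from matplotlib.path import Path as MplPath

        rng = np.random.default_rng(9)
        pa = np.column_stack([rng.uniform(1, 119, 400), rng.uniform(1, 119, 400)])
        pb = pa + rng.normal(0, 8, (400, 2))
        pb = np.clip(pb, 0.5, 119.5)
        a, b = make_track(pa, mouse_id="a"), make_track(pb, mouse_id="b")
        got = proximity_time(a, b, layout, min_s=0.0)
        count = 0
        for i in range(400):
            if np.hypot(*(pa[i] - pb[i])) >= 10.0:
                continue
            for r in layout.proximity_rois:
                path = MplPath(np.asarray(r.vertices))
                if path.contains_point(pa[i], radius=1e-9) and path.contains_point(
                    pb[i], radius=1e-9
                ):
                    count += 1
                    break
        assert got == pytest.approx(count / FPS)

    def test_mismatched_lengths_error(self, layout):
        a = make_track(np.zeros((10, 2)) + 30, mouse_id="a")
        b = make_track(np.zeros((12, 2)) + 30, mouse_id="b")
        with pytest.raises(ValueError):
            proximity_time(a, b, layout)


class TestInvariants:
    def test_hiding_bounded_by_window(self, layout):
        rng = np.random.default_rng(2)
        path = np.column_stack([rng.uniform(0, 120, 500), rng.uniform(0, 120, 500)])
        lab = roi_labels(make_track(path), layout)
        w = (0.0, 500 / FPS)
        assert 0 <= hiding_time(lab, layout, w) <= w[1]

    def test_exploration_bounded_by_compartment_time(self, layout):
        from territory.metrics import compartment_time

        rng = np.random.default_rng(7)
        path = np.column_stack([rng.uniform(0, 120, 600), rng.uniform(0, 120, 600)])
        lab = roi_labels(make_track(path), layout)
        assert exploration_time(lab, layout, 1) <= compartment_time(lab, layout, 2) + 1e-9

    def test_rigid_translation_invariance(self):
        # same custom refuge at two offsets; track shifted jointly
        def mini_layout(dx, dy):
            rois = (
                ROI("c1", "compartment", ((0, 0), (120, 0), (120, 60), (0, 60)), 1),
                ROI("c2", "compartment", ((0, 60), (120, 60), (120, 120), (0, 120)), 2),
                ROI(
                    "ref",
                    "corner",
                    tuple((x + dx, y + dy) for x, y in ((10, 10), (20, 10), (20, 20), (10, 20))),
                    1,
                ),
            )
            return ArenaLayout(frame_rate_hz=FPS, rois=rois)

        # slow sweep through the refuge so dwell bouts survive the 1 s filter
        base = np.column_stack([np.linspace(5, 40, 300), np.full(300, 15.0)])
        t0 = hiding_time(
            roi_labels(make_track(base), mini_layout(0, 0)), mini_layout(0, 0)
        )
        t1 = hiding_time(
            roi_labels(make_track(base + [7.0, 11.0]), mini_layout(7.0, 11.0)),
            mini_layout(7.0, 11.0),
        )
        assert t0 == pytest.approx(t1)
        assert t0 > 0

    def test_full_metric_summary(self, layout):
        segs = [(30, (30.0, 30.0)), (20, (4.0, 4.0)), (10, (30.0, 90.0))]
        tm = compute_trajectory_metrics(
            make_track(scripted_path(segs)), layout, 1, (0.0, 60.0)
        )
        assert tm.hiding_s == pytest.approx(20.0)
        assert tm.exploration_s == pytest.approx(10.0)
        assert tm.locomotion_cm > 0
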