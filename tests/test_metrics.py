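"""Frame-count MAPE, event matching, class collapse, time-normalized bins."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from eatsound.io import IntervalAnnotation, Segment
from eatsound.metrics import (EventTallies, FrameCounts, collapse_3class,
                              collapse_frames_3class, mape, match_events,
                              prf1, time_normalized_report)


def _ann(*segs):
    ann = IntervalAnnotation.__new__(IntervalAnnotation)
    ann.segments = [Segment(*s) for s in segs]
    return ann


class TestMape:
    def test_perfect_estimate(self):
        fc = FrameCounts()
        fc.add("r1", "L", 10, 10)
        fc.add("r1", "R", 7, 7)
        assert mape(fc) == 0.0

    def test_worked_example(self):
        fc = FrameCounts()
        fc.add("r1", "L", 10, 5)
        fc.add("r1", "R", 20, 30)
        assert mape(fc) == pytest.approx(50.0)

    def test_zero_reference_entries_excluded(self):
        fc = FrameCounts()
        fc.add("r1", "L", 10, 5)
        fc.add("r1", "F", 0, 3)
        assert mape(fc) == pytest.approx(50.0)

    def test_all_zero_reference_rejected(self):
        fc = FrameCounts()
        fc.add("r1", "L", 0, 5)
        with pytest.raises(ValueError, match="no valid entries"):
            mape(fc)

    @given(scale=st.integers(min_value=1, max_value=50))
    @settings(max_examples=20, deadline=None)
    def test_scale_free(self, scale):
        a = FrameCounts()
        b = FrameCounts()
        for i, (ak, fk) in enumerate([(3, 5), (11, 7), (20, 20)]):
            a.add("r", str(i), ak, fk)
            b.add("r", str(i), ak * scale, fk * scale)
        assert mape(a) == pytest.approx(mape(b))


class TestMatchEvents:
    def test_any_overlap_is_detection(self):
        t = match_events(_ann((1.0, 1.4, "L")), _ann((1.3, 1.6, "L")))
        assert t.tallies["L"] == {"tp": 1, "fp": 0, "fn": 0}

    def test_identity_is_perfect(self):
        ann = _ann((0.0, 0.5, "F"), (1.0, 1.2, "L"), (2.0, 2.4, "S"))
        scores = prf1(match_events(ann, ann))
        assert scores["overall"] == {"recall": 1.0, "precision": 1.0, "f1": 1.0}

    def test_class_conditional_overlap(self):
        t = match_events(_ann((1.0, 1.4, "L")), _ann((1.0, 1.4, "R")))
        assert t.tallies["L"]["fn"] == 1
        assert t.tallies["R"]["fp"] == 1
        assert t.tallies["L"]["tp"] == t.tallies["R"]["tp"] == 0

    def test_symmetry_under_ref_est_swap(self, rng):
        def random_ann():
            segs = []
            t = 0.0
            for _ in range(8):
                t += rng.uniform(0.05, 0.3)
                d = rng.uniform(0.05, 0.4)
                segs.append((t, t + d, str(rng.choice(list("LRFS")))))
                t += d
            return _ann(*segs)

        for _ in range(10):
            a, b = random_ann(), random_ann()
            ab = match_events(a, b)
            ba = match_events(b, a)
            for lab in ab.tallies:
                assert ab.tallies[lab]["fn"] == ba.tallies[lab]["fp"]
                assert ab.tallies[lab]["fp"] == ba.tallies[lab]["fn"]


class TestPrf1:
    def test_worked_example(self):
        t = EventTallies()
        t.add("L", tp=8, fp=2, fn=2)
        s = prf1(t)["L"]
        assert s == {"recall": 0.8, "precision": 0.8,
                     "f1": pytest.approx(0.8)}

    def test_perfect(self):
        t = EventTallies()
        t.add("S", tp=5)
        assert prf1(t)["S"] == {"recall": 1.0, "precision": 1.0, "f1": 1.0}

    def test_degenerate_zero_rule(self):
        t = EventTallies()
        t.add("F", tp=0, fp=3, fn=2)
        assert prf1(t)["F"] == {"recall": 0.0, "precision": 0.0, "f1": 0.0}


class TestCollapse:
    def test_frame_mapping(self):
        assert collapse_frames_3class(["L", "R", "F", "S", "O"]) == \
            ["chewing", "chewing", "chewing", "swallowing", "others"]

    def test_adjacent_chewing_segments_coalesce(self):
        ann = _ann((0.0, 0.5, "L"), (0.5, 1.0, "R"), (1.2, 1.5, "S"))
        got = collapse_3class(ann)
        assert [(s.start, s.end, s.label) for s in got.segments] == \
            [(0.0, 1.0, "chewing"), (1.2, 1.5, "swallowing")]

    def test_side_confusion_becomes_3class_hit(self):
        ref = _ann((1.0, 1.4, "L"))
        est = _ann((1.0, 1.4, "R"))
        five = prf1(match_events(ref, est))["overall"]
        three = prf1(match_events(collapse_3class(ref),
                                  collapse_3class(est)))["overall"]
        assert five["f1"] == 0.0
        assert three["f1"] == 1.0

    def test_3class_recall_never_below_5class(self, rng):
        for _ in range(15):
            def random_ann():
                segs = []
                t = 0.0
                for _ in range(10):
                    t += rng.uniform(0.05, 0.2)
                    d = rng.uniform(0.05, 0.3)
                    segs.append((t, t + d, str(rng.choice(list("LRFS")))))
                    t += d
                return _ann(*segs)
            ref, est = random_ann(), random_ann()
            r5 = prf1(match_events(ref, est))["overall"]["recall"]
            r3 = prf1(match_events(collapse_3class(ref),
                                   collapse_3class(est)))["overall"]["recall"]
            assert r3 >= r5 - 1e-12


class TestTimeNormalized:
    def test_perfect_detection_all_bins(self):
        segs = [(i * 0.4, i * 0.4 + 0.2, "L") for i in range(10)]
        segs.append((4.0, 4.3, "S"))
        ref = _ann(*segs)
        report = time_normalized_report(ref, ref, bins=5)
        assert len(report) == 5
        assert all(b["f1"] == 1.0 for b in report)

    def test_bout_bin_arithmetic(self):
        # one bout of 10 s -> bins of 2 s; an event starting at exactly 4.0
        # lands in bin 2 (later bin on the boundary)
        ref = _ann((0.0, 0.2, "L"), (4.0, 4.2, "L"), (9.0, 9.5, "L"),
                   (10.0, 10.4, "S"))
        est = _ann((4.0, 4.2, "L"))
        report = time_normalized_report(ref, est, bins=5,
                                        recording_end=10.4)
        # the bout is [0, 10): only bin 2 has a hit
        hit_bins = [i for i, b in enumerate(report) if b["f1"] > 0]
        assert hit_bins == [2]

    def test_no_swallow_single_bout(self):
        ref = _ann((0.0, 0.2, "L"), (0.9, 1.1, "R"))
        report = time_normalized_report(ref, ref, bins=5, recording_end=1.2)
        assert len(report) == 5
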