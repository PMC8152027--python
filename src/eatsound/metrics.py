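"""Evaluation protocol: frame-count MAPE, any-overlap event matching,
precision/recall/F1, the 5-to-3-class collapse, and time-normalized reports.

Two complementary views are scored.  Frame view: per (recording, class) the
reference frame count A_k is compared with the estimated frame count F_k via
the mean absolute percentage error, MAPE = 100/N * sum |A_k - F_k| / A_k over
entries with A_k > 0.  Event view: a reference event counts as detected when
at least one estimated event of the same class overlaps it in time (any
overlap, however small); recall uses reference-side counts and precision
estimate-side counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .io import IntervalAnnotation, Segment

__all__ = ["FrameCounts", "EventTallies", "mape", "match_events", "prf1",
           "collapse_3class", "collapse_frames_3class",
           "time_normalized_report", "frame_counts_from_classes"]

log = logging.getLogger(__name__)

THREE_CLASS = {"L": "chewing", "R": "chewing", "F": "chewing",
               "S": "swallowing", "O": "others"}


@dataclass
class FrameCounts:
    """Reference (A_k) and estimated (F_k) frame counts per (recording, class)."""

    entries: Dict[Tuple[str, str], Tuple[int, int]] = field(default_factory=dict)

    def add(self, recording: str, label: str, reference: int, estimated: int) -> None:
        if reference < 0 or estimated < 0:
            raise ValueError("frame counts must be >= 0")
        self.entries[(recording, label)] = (int(reference), int(estimated))

    def update_from_classes(self, recording: str, ref: Sequence[str],
                            est: Sequence[str]) -> None:
        for (rec_id, label), (a, f) in frame_counts_from_classes(
                recording, ref, est).entries.items():
            self.entries[(rec_id, label)] = (a, f)

    def __len__(self) -> int:
        return len(self.entries)


def frame_counts_from_classes(recording: str, ref: Sequence[str],
                              est: Sequence[str]) -> FrameCounts:
    """Per-class frame counts of one recording's reference/estimated tracks."""
    if len(ref) != len(est):
        raise ValueError("reference and estimated tracks differ in length")
    fc = FrameCounts()
    labels = sorted(set(ref) | set(est))
    for lab in labels:
        a = sum(1 for x in ref if x == lab)
        f = sum(1 for x in est if x == lab)
        fc.add(recording, lab, a, f)
    return fc


def mape(counts: FrameCounts) -> float:
    """Mean absolute percentage error over entries with A_k > 0 (percent)."""
    valid = [(a, f) for (a, f) in counts.entries.values() if a > 0]
    skipped = len(counts.entries) - len(valid)
    if skipped:
        log.info("mape: excluded %d entries with zero reference frames", skipped)
    if not valid:
        raise ValueError("no valid entries (all reference counts are zero)")
    errs = [abs(a - f) / a for a, f in valid]
    return 100.0 * float(np.mean(errs))


@dataclass
class EventTallies:
    """Per-class TP/FP/FN counts under any-overlap matching."""

    tallies: Dict[str, Dict[str, int]] = field(default_factory=dict)

    def _ensure(self, label: str) -> Dict[str, int]:
        return self.tallies.setdefault(label, {"tp": 0, "fp": 0, "fn": 0})

    def add(self, label: str, tp: int = 0, fp: int = 0, fn: int = 0) -> None:
        d = self._ensure(label)
        d["tp"] += tp
        d["fp"] += fp
        d["fn"] += fn

    def merge(self, other: "EventTallies") -> None:
        for lab, d in other.tallies.items():
            self.add(lab, d["tp"], d["fp"], d["fn"])

    def pooled(self) -> Dict[str, int]:
        out = {"tp": 0, "fp": 0, "fn": 0}
        for d in self.tallies.values():
            for k in out:
                out[k] += d[k]
        return out


def _overlaps(a: Segment, b: Segment) -> bool:
    return a.start < b.end and b.start < a.end


def match_events(ref: IntervalAnnotation, est: IntervalAnnotation) -> EventTallies:
    """Any-overlap event matching, per class.

    A reference event is detected (not FN) when >=1 estimated event of the
    same class overlaps it; an estimated event is TP (not FP) when it
    overlaps >=1 reference event of the same class.
    """
    out = EventTallies()
    labels = {s.label for s in ref.segments} | {s.label for s in est.segments}
    for lab in sorted(labels):
        r = [s for s in ref.segments if s.label == lab]
        e = [s for s in est.segments if s.label == lab]
        tp = sum(1 for s in e if any(_overlaps(s, t) for t in r))
        fp = len(e) - tp
        fn = sum(1 for t in r if not any(_overlaps(s, t) for s in e))
        out.add(lab, tp=tp, fp=fp, fn=fn)
    return out


def prf1(tallies: EventTallies) -> Dict[str, Dict[str, float]]:
    """Recall, precision and F1 per class (0/0 -> 0), plus a pooled 'overall'."""
    def scores(d):
        tp, fp, fn = d["tp"], d["fp"], d["fn"]
        rec = tp / (tp + fn) if tp + fn else 0.0
        pre = tp / (tp + fp) if tp + fp else 0.0
        f1 = 2 * pre * rec / (pre + rec) if pre + rec else 0.0
        return {"recall": rec, "precision": pre, "f1": f1}

    out = {lab: scores(d) for lab, d in sorted(tallies.tallies.items())}
    out["overall"] = scores(tallies.pooled())
    return out


def collapse_3class(annotation: IntervalAnnotation) -> IntervalAnnotation:
    """Map 5-class segments onto {chewing, swallowing, others}.

    L, R, F -> chewing; S -> swallowing.  Adjacent segments that touch and
    share the collapsed class are coalesced.
    """
    mapped = [Segment(s.start, s.end, THREE_CLASS[s.label])
              for s in annotation.segments]
    merged: List[Segment] = []
    for s in mapped:
        if merged and merged[-1].label == s.label and s.start <= merged[-1].end:
            merged[-1] = Segment(merged[-1].start, max(merged[-1].end, s.end),
                                 s.label)
        else:
            merged.append(s)
    ann = IntervalAnnotation.__new__(IntervalAnnotation)
    ann.segments = merged          # bypass the 5-class label validator
    return ann


def collapse_frames_3class(frame_classes: Sequence[str]) -> List[str]:
    return [THREE_CLASS[c] for c in frame_classes]


def time_normalized_report(ref: IntervalAnnotation, est: IntervalAnnotation,
                           bins: int = 5, recording_end: Optional[float] = None
                           ) -> List[Dict[str, float]]:
    """Pooled P/R/F1 within equal-duration bins of each chew bout.

    A bout runs from the start of eating (or the previous swallow's end) to
    the start of the next swallow; with no swallow in the reference, the
    whole span is one bout.  Each bout is split into `bins` equal half-open
    time bins; events (reference and estimated) are assigned to bins by their
    start time, an event exactly on a boundary going to the later bin.
    """
    if not ref.segments:
        raise ValueError("empty reference annotation")
    t_begin = ref.segments[0].start
    t_end = recording_end if recording_end is not None else max(
        [s.end for s in ref.segments] + [s.end for s in est.segments] or [0.0])
    swallows = [s for s in ref.segments if s.label == "S"]
    bouts = []
    cursor = t_begin
    for sw in swallows:
        if sw.start > cursor:
            bouts.append((cursor, sw.start))
        cursor = sw.end
    if cursor < t_end:
        bouts.append((cursor, t_end))
    if not bouts:
        bouts = [(t_begin, max(t_end, t_begin + 1e-9))]

    per_bin = [EventTallies() for _ in range(bins)]
    for lo, hi in bouts:
        width = (hi - lo) / bins
        if width <= 0:
            continue
        for i in range(bins):
            b_lo = lo + i * width
            b_hi = lo + (i + 1) * width if i < bins - 1 else hi

            def select(ann):
                segs = [s for s in ann.segments
                        if b_lo <= s.start < b_hi or
                        (i == bins - 1 and s.start == hi)]
                out = IntervalAnnotation.__new__(IntervalAnnotation)
                out.segments = segs
                return out

            per_bin[i].merge(match_events(select(ref), select(est)))
    return [prf1(t)["overall"] for t in per_bin]
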