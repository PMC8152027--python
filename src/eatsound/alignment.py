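"""CTC forced alignment and the event-clip database.

Weak labels carry event order but no timing.  A CTC-trained model's frame
posteriors let us recover timing: the Viterbi best path through the CTC
trellis *constrained to the weak label sequence* assigns each event a start
frame.  Recordings are then cut at event starts — each clip runs from its
event's onset to the next event's onset (the last to the recording end) — and
the clips are indexed by (speaker, food, event type) to form the raw material
for concatenative data augmentation.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .features import FeatureConfig, extract_features
from .io import (DatasetManifest, StereoRecording, WeakLabelSequence,
                 read_wav, read_weak_labels, write_wav)
from .model import (HybridModel, PosteriorTrack, Vocab, _extended,
                    _as_ctc_ids, ctc_feasible)

__all__ = ["EventAlignment", "EventClip", "ClipDB", "forced_align",
           "cut_clips", "build_clipdb"]

NEG_INF = -np.inf


@dataclass
class EventAlignment:
    """Per-event (token, start_frame) pairs in weak-label order."""

    events: List[Tuple[str, int]]

    def __post_init__(self):
        starts = [s for _, s in self.events]
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise ValueError("start frames must be strictly increasing")

    def __len__(self) -> int:
        return len(self.events)


@dataclass
class EventClip:
    """An alignment-cut waveform snippet with its source position."""

    waveform: np.ndarray        # 2 x s
    token: str
    t_i: float                  # seconds from the source recording's start
    speaker: str
    food: str
    rate: int = 22050

    def __post_init__(self):
        if self.waveform.ndim != 2 or self.waveform.shape[0] != 2:
            raise ValueError("clip waveform must be 2 x s")
        if self.t_i < 0:
            raise ValueError("t_i must be >= 0")
        if self.duration <= 0:
            raise ValueError("clip duration must be positive")

    @property
    def duration(self) -> float:
        return self.waveform.shape[1] / self.rate


class ClipDB:
    """Event clips indexed by (speaker, food, token)."""

    def __init__(self):
        self._clips: Dict[Tuple[str, str, str], List[EventClip]] = {}

    def add(self, clip: EventClip) -> None:
        key = (clip.speaker, clip.food, clip.token)
        self._clips.setdefault(key, []).append(clip)

    def get(self, speaker: str, food: str, token: str) -> List[EventClip]:
        return self._clips.get((speaker, food, token), [])

    def __len__(self) -> int:
        return sum(len(v) for v in self._clips.values())

    def keys(self):
        return self._clips.keys()

    def save(self, out_dir: str) -> str:
        """Persist as WAV clips plus a CSV index; returns the index path."""
        os.makedirs(out_dir, exist_ok=True)
        rows = []
        for i, (key, clips) in enumerate(sorted(self._clips.items())):
            for j, c in enumerate(clips):
                name = f"clip_{c.speaker}_{c.food}_{c.token}_{i:03d}_{j:04d}.wav"
                write_wav(os.path.join(out_dir, name),
                          StereoRecording(samples=c.waveform, rate=c.rate))
                rows.append({"clip": name, "token": c.token, "t_i": c.t_i,
                             "duration": c.duration, "speaker": c.speaker,
                             "food": c.food})
        index = os.path.join(out_dir, "clips.csv")
        pd.DataFrame(rows).to_csv(index, index=False)
        return index

    @classmethod
    def load(cls, index_path: str) -> "ClipDB":
        base = os.path.dirname(os.path.abspath(index_path))
        df = pd.read_csv(index_path, dtype={"speaker": str, "food": str})
        db = cls()
        for _, r in df.iterrows():
            rec = read_wav(os.path.join(base, r["clip"]))
            db.add(EventClip(waveform=rec.samples, token=r["token"],
                             t_i=float(r["t_i"]), speaker=str(r["speaker"]),
                             food=str(r["food"]), rate=rec.rate))
        return db


def forced_align(posteriors: PosteriorTrack, weak: WeakLabelSequence) -> EventAlignment:
    """Viterbi best path through the CTC trellis constrained to the target.

    Each event's start frame is the first frame on which the best path emits
    that token occurrence.  Trellis ties prefer staying in the current state
    (blank/self-loop) over advancing, making the alignment deterministic.
    """
    ids = _as_ctc_ids(weak)
    probs = posteriors.probs if isinstance(posteriors, PosteriorTrack) else np.asarray(posteriors)
    T = probs.shape[0]
    if not ctc_feasible(T, ids):
        raise ValueError("infeasible target for forced alignment")
    with np.errstate(divide="ignore"):
        lp = np.log(probs)
    ext = _extended(ids)
    S = len(ext)
    skip = np.zeros(S, dtype=bool)
    skip[2:] = (ext[2:] != Vocab.BLANK) & (ext[2:] != ext[:-2])

    delta = np.full((T, S), NEG_INF)
    back = np.zeros((T, S), dtype=np.int64)
    delta[0, 0] = lp[0, ext[0]]
    if S > 1:
        delta[0, 1] = lp[0, ext[1]]
    for t in range(1, T):
        prev = delta[t - 1]
        for s in range(S):
            # candidate predecessors ordered stay, advance, skip: argmax on
            # ties picks the first, i.e. prefer staying
            cands = [prev[s]]
            if s >= 1:
                cands.append(prev[s - 1])
            if s >= 2 and skip[s]:
                cands.append(prev[s - 2])
            k = int(np.argmax(cands))
            delta[t, s] = cands[k] + lp[t, ext[s]]
            back[t, s] = s - k

    ends = [S - 1] if S == 1 else [S - 1, S - 2]
    s = max(ends, key=lambda e: (delta[T - 1, e], -e))
    if not np.isfinite(delta[T - 1, s]):
        raise ValueError("target has zero probability under the posteriors")
    path = np.zeros(T, dtype=np.int64)
    path[T - 1] = s
    for t in range(T - 1, 0, -1):
        s = back[t, s]
        path[t - 1] = s
    starts = []
    for occ in range(len(ids)):
        state = 2 * occ + 1
        starts.append(int(np.argmax(path == state)))
    return EventAlignment(events=list(zip(list(weak.tokens), starts)))


def cut_clips(rec: StereoRecording, align: EventAlignment, hop: float,
              win: float, speaker: str = "", food: str = "") -> List[EventClip]:
    """Cut a recording at event onsets.

    Clip i spans from its event's start time (start_frame * hop) to the next
    event's start; the last clip runs to the recording end.  Audio before the
    first event is "others" and is excluded.  The cut points partition the
    recording sample-exactly.
    """
    if len(align) == 0:
        raise ValueError("empty alignment")
    bounds = [int(round(s * hop * rec.rate)) for _, s in align.events]
    bounds.append(rec.n_samples)
    clips = []
    for i, (token, start_frame) in enumerate(align.events):
        seg = rec.samples[:, bounds[i]:bounds[i + 1]]
        clips.append(EventClip(waveform=seg, token=token,
                               t_i=start_frame * hop, speaker=speaker,
                               food=food, rate=rec.rate))
    return clips


def build_clipdb(manifest: DatasetManifest, model: HybridModel,
                 feature_config: Optional[FeatureConfig] = None) -> ClipDB:
    """Align and cut every manifest recording into a clip database.

    The model is typically a CTC-trained bootstrap (alpha=1), but any
    checkpoint with a CTC head works.  Recordings whose weak labels are
    infeasible for their frame count are skipped with a warning.
    """
    fcfg = feature_config or FeatureConfig()
    db = ClipDB()
    for row in manifest:
        rec = read_wav(row.wav)
        weak = read_weak_labels(row.weak, speaker=row.speaker, food=row.food)
        fm = extract_features(rec, fcfg)
        if not ctc_feasible(fm.n_frames, weak.tokens):
            warnings.warn(f"skipping {row.wav}: infeasible weak label")
            continue
        post = model.frame_posteriors(fm)
        try:
            align = forced_align(post, weak)
        except ValueError as exc:
            warnings.warn(f"skipping {row.wav}: {exc}")
            continue
        for clip in cut_clips(rec, align, fcfg.hop, fcfg.win,
                              speaker=row.speaker, food=row.food):
            db.add(clip)
    return db
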