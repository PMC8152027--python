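"""File formats and in-memory containers for eating-sound datasets.

Recordings are two-channel 16-bit PCM WAV captured by a pair of skin-contact
microphones worn under the left and right ear (channel 0 = left microphone,
channel 1 = right).  Supervision comes in two strengths: *weak labels* are the
ordered event tokens of a recording with no timing, used for training;
*interval annotations* carry start/end times per event and are used only for
evaluation (and are emitted exactly by the synthetic generator).
"""

from __future__ import annotations

import enum
import os
from dataclasses import dataclass, field
from typing import Iterable, List, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.io import wavfile

__all__ = [
    "EventClass", "EVENT_TOKENS", "StereoRecording", "WeakLabelSequence",
    "Segment", "IntervalAnnotation", "ManifestRow", "DatasetManifest",
    "read_wav", "write_wav", "read_weak_labels", "write_weak_labels",
    "read_intervals", "write_intervals", "read_manifest", "write_manifest",
    "intervals_to_frames",
]


class EventClass(str, enum.Enum):
    """Five-way frame/event vocabulary.

    L/R are left/right chewing, F is front biting, S is swallowing and O
    ("others") covers silence and noise.  O is a valid frame class but never
    appears in a weak label sequence, which lists events only.
    """

    LEFT = "L"
    RIGHT = "R"
    FRONT = "F"
    SWALLOW = "S"
    OTHER = "O"


#: tokens allowed in weak label sequences (no O)
EVENT_TOKENS = ("L", "R", "F", "S")

_INT16_SCALE = 32768.0


@dataclass
class StereoRecording:
    """A 2xS sample array in [-1, 1] plus its sampling rate."""

    samples: np.ndarray
    rate: int = 22050

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 2 or self.samples.shape[0] != 2:
            raise ValueError("two channels required (shape 2xS)")
        if self.samples.shape[1] < 1:
            raise ValueError("recording must contain at least one sample")
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate


@dataclass
class WeakLabelSequence:
    """Ordered event tokens of one recording, without timestamps."""

    tokens: List[str]
    speaker: str = ""
    food: str = ""

    def __post_init__(self):
        bad = [t for t in self.tokens if t not in EVENT_TOKENS]
        if bad:
            raise ValueError(f"unknown token(s) in weak labels: {bad}")

    def __len__(self) -> int:
        return len(self.tokens)


class Segment(NamedTuple):
    start: float
    end: float
    label: str


@dataclass
class IntervalAnnotation:
    """Timed, typed event segments; half-open intervals [start, end)."""

    segments: List[Segment]

    def __post_init__(self):
        segs = [Segment(float(s), float(e), str(l)) for s, e, l in self.segments]
        for s in segs:
            if s.label not in EVENT_TOKENS:
                raise ValueError(f"unknown segment label {s.label!r}")
            if not s.start < s.end:
                raise ValueError(f"segment start must precede end: {s}")
        segs.sort(key=lambda s: (s.start, s.end))
        for a, b in zip(segs, segs[1:]):
            if b.start < a.end:
                raise ValueError(f"overlapping segments: {a} / {b}")
        self.segments = segs

    def tokens(self) -> List[str]:
        return [s.label for s in self.segments]

    def __len__(self) -> int:
        return len(self.segments)


@dataclass
class ManifestRow:
    wav: str
    weak: str
    strong: Optional[str]
    speaker: str
    food: str


@dataclass
class DatasetManifest:
    """Links recordings to label files plus speaker/food metadata."""

    rows: List[ManifestRow] = field(default_factory=list)

    def __post_init__(self):
        for r in self.rows:
            if not r.speaker or not r.food:
                raise ValueError("speaker and food must be non-empty")

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self):
        return iter(self.rows)

    def groups(self):
        """Yield ((speaker, food), [rows]) groups in first-seen order."""
        seen: dict = {}
        for r in self.rows:
            seen.setdefault((r.speaker, r.food), []).append(r)
        return seen.items()


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_wav(path: str) -> StereoRecording:
    """Read a two-channel PCM WAV into a StereoRecording.

    16-bit samples are scaled by 1/32768 into [-1, 1); mono files are
    rejected because the left/right microphone pair is required.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    rate, data = wavfile.read(path)
    if data.ndim != 2 or data.shape[1] != 2:
        raise ValueError(f"{path}: two channels required")
    if data.dtype == np.int16:
        x = data.astype(np.float64) / _INT16_SCALE
    elif data.dtype == np.int32:
        x = data.astype(np.float64) / 2147483648.0
    elif data.dtype in (np.float32, np.float64):
        x = data.astype(np.float64)
    else:
        raise ValueError(f"{path}: unsupported WAV encoding {data.dtype}")
    return StereoRecording(samples=x.T, rate=int(rate))


def write_wav(path: str, rec: StereoRecording) -> None:
    """Write a StereoRecording as 16-bit PCM WAV (values clipped to [-1, 1])."""
    x = np.clip(rec.samples, -1.0, 32767.0 / _INT16_SCALE)
    data = np.round(x * _INT16_SCALE).astype(np.int16)
    wavfile.write(path, rec.rate, data.T)


def read_weak_labels(path: str, speaker: str = "", food: str = "") -> WeakLabelSequence:
    """Parse one line of whitespace-separated event tokens."""
    with open(path) as fh:
        text = fh.read()
    tokens = text.split()
    if not tokens:
        raise ValueError(f"{path}: empty weak label file")
    for t in tokens:
        if t not in EVENT_TOKENS:
            raise ValueError(f"{path}: unknown token {t!r}")
    return WeakLabelSequence(tokens=tokens, speaker=speaker, food=food)


def write_weak_labels(path: str, weak: WeakLabelSequence) -> None:
    with open(path, "w") as fh:
        fh.write(" ".join(weak.tokens) + "\n")


def read_intervals(path: str) -> IntervalAnnotation:
    """Read a 3-column TSV (start_s, end_s, token); a header row is optional."""
    segs = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t")
            if parts[0].lower().startswith("start"):
                continue
            if len(parts) != 3:
                raise ValueError(f"{path}: expected 3 columns, got {parts!r}")
            segs.append(Segment(float(parts[0]), float(parts[1]), parts[2]))
    return IntervalAnnotation(segments=segs)


def write_intervals(path: str, ann: IntervalAnnotation) -> None:
    with open(path, "w") as fh:
        fh.write("start_s\tend_s\ttoken\n")
        for s in ann.segments:
            fh.write(f"{s.start:.6f}\t{s.end:.6f}\t{s.label}\n")


_MANIFEST_COLS = ["wav", "weak", "strong", "speaker", "food"]


def read_manifest(path: str, check_files: bool = True) -> DatasetManifest:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _MANIFEST_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: manifest missing columns {missing}")
    base = os.path.dirname(os.path.abspath(path))

    def resolve(p: str) -> str:
        return p if (not p or os.path.isabs(p)) else os.path.join(base, p)

    rows = []
    for _, r in df.iterrows():
        row = ManifestRow(wav=resolve(r["wav"]), weak=resolve(r["weak"]),
                          strong=resolve(r["strong"]) or None,
                          speaker=r["speaker"], food=r["food"])
        if check_files:
            for p in (row.wav, row.weak, row.strong):
                if p and not os.path.exists(p):
                    raise FileNotFoundError(p)
        rows.append(row)
    return DatasetManifest(rows=rows)


def write_manifest(path: str, manifest: DatasetManifest, relative_to: Optional[str] = None) -> None:
    recs = []
    for r in manifest.rows:
        def rel(p):
            if not p:
                return ""
            return os.path.relpath(p, relative_to) if relative_to else p
        recs.append({"wav": rel(r.wav), "weak": rel(r.weak),
                     "strong": rel(r.strong), "speaker": r.speaker, "food": r.food})
    pd.DataFrame(recs, columns=_MANIFEST_COLS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# interval -> frame discretization
# ---------------------------------------------------------------------------

def intervals_to_frames(annotation: IntervalAnnotation, n_frames: int,
                        hop: float, win: float, t0: float = 0.0) -> List[str]:
    """Discretize timed segments onto the analysis frame grid.

    Frame t spans ``[t0 + t*hop, t0 + t*hop + win)``.  The frame takes the
    class of the segment with the largest temporal overlap, provided that
    overlap strictly exceeds half the window (strict majority); otherwise the
    frame is O.  Among equal overlaps the earlier-starting segment wins.
    """
    out = []
    segs = annotation.segments
    for t in range(n_frames):
        lo = t0 + t * hop
        hi = lo + win
        best_label, best_ov, best_start = "O", 0.0, None
        for s in segs:
            ov = min(hi, s.end) - max(lo, s.start)
            if ov <= 0:
                continue
            if ov > best_ov or (ov == best_ov and
                                (best_start is None or s.start < best_start)):
                best_label, best_ov, best_start = s.label, ov, s.start
        # strict majority with a 1 ns guard so exactly-half overlaps are O
        # regardless of floating-point representation of the grid
        out.append(best_label if best_ov > 0.5 * win + 1e-9 else "O")
    return out
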