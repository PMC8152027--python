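"""Frame-level smoothing and the single-call detector.

The CTC head's frame posteriors are turned into a smoothed per-frame class
track with the double-threshold rule: frames whose class probability exceeds
phi_high seed a detection, and each seed region is extended left and right
through contiguous frames above phi_low.  This suppresses spurious one-frame
chewing-side flips.  Frames active for more than one class take the active
class with the highest posterior; frames active for none are O.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
from scipy import ndimage

from .features import FeatureConfig, extract_features
from .io import IntervalAnnotation, Segment, StereoRecording
from .model import HybridModel, PosteriorTrack, Vocab

__all__ = ["SmoothingConfig", "DetectionResult", "double_threshold",
           "resolve_frames", "detect", "frames_to_intervals"]


@dataclass
class SmoothingConfig:
    phi_low: float = 0.2
    phi_high: float = 0.5

    def __post_init__(self):
        if not (0.0 <= self.phi_low <= self.phi_high <= 1.0):
            raise ValueError("need 0 <= phi_low <= phi_high <= 1")


@dataclass
class DetectionResult:
    posteriors: PosteriorTrack
    tokens: List[str]           # decoded event sequence (joint beam search)
    frame_classes: List[str]    # smoothed per-frame classes
    frame_times: np.ndarray

    def __post_init__(self):
        T = self.posteriors.n_frames
        if len(self.frame_classes) != T or len(self.frame_times) != T:
            raise ValueError("all frame tracks must share one length")


def double_threshold(track: np.ndarray, phi_low: float, phi_high: float) -> np.ndarray:
    """Two-pass activity mask over one class's probability track.

    Frames strictly above phi_high are seeds; each seed's contiguous run of
    frames strictly above phi_low becomes active.  Returns a boolean mask.
    """
    if not (0.0 <= phi_low <= phi_high <= 1.0):
        raise ValueError("need 0 <= phi_low <= phi_high <= 1")
    track = np.asarray(track, dtype=np.float64)
    seeds = track > phi_high
    passable = track > phi_low
    if not seeds.any():
        return np.zeros_like(seeds)
    labels, n = ndimage.label(passable)
    keep = np.unique(labels[seeds])
    return np.isin(labels, keep[keep > 0])


def resolve_frames(posteriors: PosteriorTrack, config: Optional[SmoothingConfig] = None
                   ) -> List[str]:
    """Smoothed per-frame classes from the 5-way posterior track.

    The double threshold runs on each of the four event tracks ("others" is
    the blank posterior and is never smoothed directly); frames active for
    several classes take the one with the highest posterior, frames active
    for none are O.
    """
    cfg = config or SmoothingConfig()
    p = posteriors.probs
    T = p.shape[0]
    active = np.zeros((T, Vocab.N_CTC), dtype=bool)
    for k in range(1, Vocab.N_CTC):
        active[:, k] = double_threshold(p[:, k], cfg.phi_low, cfg.phi_high)
    out = []
    for t in range(T):
        if not active[t, 1:].any():
            out.append("O")
        else:
            masked = np.where(active[t], p[t], -1.0)
            masked[0] = -1.0
            out.append(Vocab.CTC_SYMBOLS[int(np.argmax(masked))])
    return out


def frames_to_intervals(frame_classes: List[str], hop: float, win: float,
                        keep_other: bool = False) -> IntervalAnnotation:
    """Merge consecutive identical frame classes into timed segments.

    Segment boundaries fall on frame-start times; the final segment extends
    one window beyond its last frame's start.
    """
    segs = []
    T = len(frame_classes)
    t = 0
    while t < T:
        label = frame_classes[t]
        u = t
        while u + 1 < T and frame_classes[u + 1] == label:
            u += 1
        if label != "O" or keep_other:
            segs.append(Segment(t * hop, u * hop + win, label))
        t = u + 1
    # trim abutting overlaps introduced by the window tail
    trimmed = []
    for i, s in enumerate(segs):
        end = s.end
        if i + 1 < len(segs) and segs[i + 1].start < end:
            end = segs[i + 1].start
        trimmed.append(Segment(s.start, end, s.label))
    return IntervalAnnotation(segments=[s for s in trimmed if s.end > s.start])


def detect(rec: StereoRecording, model: HybridModel,
           feature_config: Optional[FeatureConfig] = None,
           smoothing: Optional[SmoothingConfig] = None,
           beam: Optional[int] = None, alpha: Optional[float] = None
           ) -> DetectionResult:
    """Full detector: features -> posteriors -> decoded tokens + frame classes."""
    fcfg = feature_config or FeatureConfig()
    fm = extract_features(rec, fcfg)
    post = model.frame_posteriors(fm)
    tokens = model.decode_joint(fm, beam=beam, alpha=alpha)
    frames = resolve_frames(post, smoothing)
    return DetectionResult(posteriors=post, tokens=tokens,
                           frame_classes=frames, frame_times=fm.frame_times)
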