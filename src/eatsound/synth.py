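"""Seeded synthetic generator of two-channel eating-sound recordings.

No public corpus of under-ear eating sounds exists, so this module fabricates
recordings with exactly known weak and strong labels that reproduce the
statistical structure the detector and the augmenter rely on:

* a bout grammar — an optional front bite opens a bout, chews persist on one
  side with a configurable probability, a swallow arrives after a
  Normal(mu, sigma) number of chews and closes the bout;
* left/right channel asymmetry — the channel on the chewing side is louder
  (default +6 dB) and *leads* the opposite channel by a couple of samples,
  matching the inter-ear path difference the cross-correlation features pick
  up;
* within-bout amplitude decay — early chews (intact food) are louder than
  late ones (crushed food), by a per-event decay factor;
* silence between events plus stationary background noise at a target SNR.

Event spectra are simple band-limited noise bursts (chews 500-4000 Hz,
swallows 50-500 Hz, bites broadband clicks); they are caricatures, chosen so
that the classes are acoustically separable in the same ways real events are
(band, duration, stereo asymmetry), not physical simulations.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import List, Optional, Tuple

import numpy as np
from scipy import signal as sps

from .io import (DatasetManifest, IntervalAnnotation, ManifestRow, Segment,
                 StereoRecording, WeakLabelSequence, write_intervals,
                 write_manifest, write_wav, write_weak_labels)

__all__ = ["SynthConfig", "generate_recording", "generate_dataset"]


@dataclass
class SynthConfig:
    rate: int = 22050
    # per-class acoustic templates
    chew_duration: Tuple[float, float] = (0.06, 0.15)      # seconds
    chew_band: Tuple[float, float] = (500.0, 4000.0)       # Hz
    bite_duration: Tuple[float, float] = (0.03, 0.08)
    swallow_duration: Tuple[float, float] = (0.2, 0.4)
    swallow_band: Tuple[float, float] = (50.0, 500.0)
    # stereo asymmetry of side events
    side_gain_db: float = 6.0      # ipsilateral channel is this much louder
    side_lag: int = 2              # contralateral channel delay, samples
    # sequence structure
    side_persistence: float = 0.8  # P(repeat previous chew side)
    front_bite_prob: float = 0.7   # P(bout opens with F)
    swallow_mu: float = 12.0       # chews per swallow
    swallow_sigma: float = 3.0
    swallow_enabled: bool = True   # off for chewing gum
    bout_decay: float = 0.97       # amplitude factor per event within a bout
    base_amplitude: float = 0.4
    gap_range: Tuple[float, float] = (0.12, 0.35)          # inter-event silence
    noise_snr_db: float = 20.0
    seed: int = 0

    def __post_init__(self):
        for name in ("chew_duration", "bite_duration", "swallow_duration",
                     "gap_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"{name} must be positive and ordered")
        if not (0.0 <= self.side_persistence <= 1.0):
            raise ValueError("side_persistence must lie in [0, 1]")
        if self.side_gain_db < 0:
            raise ValueError("side_gain_db must be >= 0")
        if self.swallow_enabled and self.swallow_mu <= 0:
            raise ValueError("swallow_mu must be positive")


def _burst(rng: np.random.Generator, n: int, rate: int,
           band: Optional[Tuple[float, float]]) -> np.ndarray:
    """Band-limited noise burst with an exponential decay envelope."""
    x = rng.standard_normal(n)
    if band is not None:
        nyq = rate / 2.0
        lo = max(band[0] / nyq, 1e-4)
        hi = min(band[1] / nyq, 0.999)
        b, a = sps.butter(4, [lo, hi], btype="bandpass")
        x = sps.lfilter(b, a, x)
    env = np.exp(-3.0 * np.arange(n) / n)
    x = x * env
    peak = np.abs(x).max()
    return x / peak if peak > 0 else x


def _event_waveform(token: str, cfg: SynthConfig, rng: np.random.Generator,
                    amplitude: float, side: Optional[str]) -> np.ndarray:
    """Stereo (2 x n) waveform of one event at the given amplitude."""
    rate = cfg.rate
    if token in ("L", "R"):
        dur = rng.uniform(*cfg.chew_duration)
        mono = _burst(rng, int(dur * rate), rate, cfg.chew_band)
    elif token == "F":
        dur = rng.uniform(*cfg.bite_duration)
        mono = _burst(rng, int(dur * rate), rate, None)
    else:  # S
        dur = rng.uniform(*cfg.swallow_duration)
        mono = _burst(rng, int(dur * rate), rate, cfg.swallow_band)
    mono = mono * amplitude
    n = len(mono)
    out = np.zeros((2, n))
    if token in ("L", "R"):
        g = 10.0 ** (cfg.side_gain_db / 20.0)
        lag = cfg.side_lag
        delayed = np.zeros(n)
        delayed[lag:] = mono[:n - lag] if lag > 0 else mono
        ipsi = 0 if token == "L" else 1
        out[ipsi] = g * mono
        out[1 - ipsi] = delayed
    else:
        out[0] = mono
        out[1] = mono
    return out


def _event_sequence(cfg: SynthConfig, n_events: int,
                    rng: np.random.Generator) -> List[str]:
    """Bout grammar: optional F, persistent-side chews, S per spacing model."""
    tokens: List[str] = []
    bout_start = True
    side = None
    k = None
    since_swallow = 0
    while len(tokens) < n_events:
        if cfg.swallow_enabled and k is not None and since_swallow >= k:
            tokens.append("S")
            bout_start, side, k, since_swallow = True, None, None, 0
            continue
        if bout_start:
            if cfg.swallow_enabled:
                k = max(1, int(round(rng.normal(cfg.swallow_mu,
                                                cfg.swallow_sigma))))
            bout_start = False
            if rng.random() < cfg.front_bite_prob:
                tokens.append("F")
                since_swallow += 1
                continue
        if side is None or rng.random() >= cfg.side_persistence:
            side = str(rng.choice(["L", "R"]))
        tokens.append(side)
        since_swallow += 1
    return tokens


def generate_recording(cfg: SynthConfig, n_events: int,
                       rng: np.random.Generator
                       ) -> Tuple[StereoRecording, WeakLabelSequence, IntervalAnnotation]:
    """One recording with exact labels; identical rng state -> identical output."""
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    tokens = _event_sequence(cfg, n_events, rng)
    rate = cfg.rate
    chunks: List[np.ndarray] = []
    segments: List[Segment] = []
    pos = 0
    amplitude = cfg.base_amplitude
    for tok in tokens:
        gap = int(rng.uniform(*cfg.gap_range) * rate)
        chunks.append(np.zeros((2, gap)))
        pos += gap
        wav = _event_waveform(tok, cfg, rng, amplitude, None)
        chunks.append(wav)
        segments.append(Segment(pos / rate, (pos + wav.shape[1]) / rate, tok))
        pos += wav.shape[1]
        if tok == "S":
            amplitude = cfg.base_amplitude        # new bout: reset decay
        else:
            amplitude *= cfg.bout_decay
    tail = int(rng.uniform(*cfg.gap_range) * rate)
    chunks.append(np.zeros((2, tail)))
    x = np.concatenate(chunks, axis=1)
    sig_rms = np.sqrt((x ** 2).sum() / max((np.abs(x) > 0).sum(), 1))
    noise_rms = sig_rms * 10.0 ** (-cfg.noise_snr_db / 20.0)
    x = x + noise_rms * rng.standard_normal(x.shape)
    np.clip(x, -1.0, 1.0, out=x)
    rec = StereoRecording(samples=x, rate=rate)
    weak = WeakLabelSequence(tokens=tokens)
    return rec, weak, IntervalAnnotation(segments=segments)


def generate_dataset(cfg: SynthConfig, n_speakers: int, n_recordings: int,
                     out_dir: str, food: str = "cracker",
                     events_range: Tuple[int, int] = (8, 16),
                     prefix: str = "rec") -> DatasetManifest:
    """Write a synthetic dataset: WAVs, weak labels, intervals, manifest.

    Each speaker gets a jittered copy of the template parameters (gain, gap
    tempo, chew band) drawn from a per-speaker sub-seed, so speakers differ
    reproducibly.  `events_range` bounds the per-recording event count
    (inclusive).  Food "gum" disables swallowing.
    """
    os.makedirs(out_dir, exist_ok=True)
    rows: List[ManifestRow] = []
    for s in range(n_speakers):
        speaker = f"s{s:02d}"
        srng = np.random.default_rng([cfg.seed, s])
        scfg = replace(
            cfg,
            base_amplitude=cfg.base_amplitude * srng.uniform(0.8, 1.2),
            bout_decay=min(cfg.bout_decay * srng.uniform(0.99, 1.01), 0.999),
            gap_range=tuple(np.array(cfg.gap_range) * srng.uniform(0.85, 1.15)),
            chew_band=(cfg.chew_band[0] * srng.uniform(0.9, 1.1),
                       cfg.chew_band[1] * srng.uniform(0.9, 1.1)),
            swallow_enabled=cfg.swallow_enabled and food != "gum",
        )
        for r in range(n_recordings):
            rng = np.random.default_rng([cfg.seed, s, r])
            n_events = int(rng.integers(events_range[0], events_range[1] + 1))
            rec, weak, ann = generate_recording(scfg, n_events, rng)
            weak.speaker, weak.food = speaker, food
            stem = f"{prefix}_{speaker}_{r:04d}"
            wav = os.path.join(out_dir, stem + ".wav")
            weak_path = os.path.join(out_dir, stem + ".weak.txt")
            strong_path = os.path.join(out_dir, stem + ".intervals.tsv")
            write_wav(wav, rec)
            write_weak_labels(weak_path, weak)
            write_intervals(strong_path, ann)
            rows.append(ManifestRow(wav=wav, weak=weak_path, strong=strong_path,
                                    speaker=speaker, food=food))
    manifest = DatasetManifest(rows=rows)
    write_manifest(os.path.join(out_dir, "manifest.csv"), manifest,
                   relative_to=out_dir)
    return manifest
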