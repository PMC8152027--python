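"""Acoustic features for under-ear eating sounds.

Each recording is framed with an 80 ms window and 40 ms hop.  Per frame we
compute 39 MFCC-family coefficients of the left+right channel sum (12 MFCCs
plus RMS, with delta and delta-delta appended) and a short normalized
cross-correlation curve between the two channels at small integer sample lags
(default +/-3 samples, i.e. 7 points at 22.05 kHz).  The channel sum enhances
the common chewing signal; the cross-correlation carries the inter-ear level
and timing asymmetry that distinguishes left from right chewing.

Lag sign convention: positive lag means the right channel's content occurs
*later* than the left's, so a left-side event (left microphone leads) peaks at
a positive lag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.fft import dct, rfft

from .io import StereoRecording

__all__ = ["FeatureConfig", "FeatureMatrix", "frame_signal",
           "mfcc_sum_features", "cross_correlation_features",
           "extract_features", "save_features", "load_features"]


@dataclass
class FeatureConfig:
    win: float = 0.08           # analysis window, seconds
    hop: float = 0.04           # frame shift, seconds
    n_mfcc: int = 12            # cepstral coefficients (c1..c12)
    n_mel: int = 26             # mel filters, 0 Hz .. Nyquist
    fft_size: int = 2048
    cc_points: int = 7          # odd number of cross-correlation lags
    pre_emphasis: float = 0.0   # off by default

    def __post_init__(self):
        if not (self.win > self.hop > 0):
            raise ValueError("need win > hop > 0")
        if self.cc_points < 1 or self.cc_points % 2 == 0:
            raise ValueError("cc_points must be odd and >= 1")

    @property
    def n_dims(self) -> int:
        return 3 * (self.n_mfcc + 1) + self.cc_points

    def n_win(self, rate: int) -> int:
        return int(round(self.win * rate))

    def n_hop(self, rate: int) -> int:
        return int(round(self.hop * rate))


@dataclass
class FeatureMatrix:
    values: np.ndarray          # T x D
    frame_times: np.ndarray     # frame start times, seconds
    rate: int = 22050

    def __post_init__(self):
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains NaN/Inf")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_dims(self) -> int:
        return self.values.shape[1]


def frame_signal(x: np.ndarray, win: float, hop: float, rate: int) -> np.ndarray:
    """Slice a 1-d signal into overlapping frames (trailing partial dropped)."""
    x = np.asarray(x)
    n_win = int(round(win * rate))
    n_hop = int(round(hop * rate))
    if len(x) < n_win:
        raise ValueError(f"signal shorter than one window ({len(x)} < {n_win})")
    n_frames = 1 + (len(x) - n_win) // n_hop
    idx = n_hop * np.arange(n_frames)[:, None] + np.arange(n_win)[None, :]
    return x[idx]


def _mel(f):
    return 2595.0 * np.log10(1.0 + f / 700.0)


def _mel_inv(m):
    return 700.0 * (10.0 ** (m / 2595.0) - 1.0)


def _mel_filterbank(n_mel: int, fft_size: int, rate: int) -> np.ndarray:
    """Triangular mel filters spanning 0 Hz to Nyquist; (n_mel, fft/2+1)."""
    n_bins = fft_size // 2 + 1
    pts = _mel_inv(np.linspace(_mel(0.0), _mel(rate / 2.0), n_mel + 2))
    bins = np.floor((fft_size + 1) * pts / rate).astype(int)
    fb = np.zeros((n_mel, n_bins))
    for i in range(n_mel):
        lo, mid, hi = bins[i], bins[i + 1], bins[i + 2]
        if mid > lo:
            fb[i, lo:mid] = (np.arange(lo, mid) - lo) / (mid - lo)
        if hi > mid:
            fb[i, mid:hi] = (hi - np.arange(mid, hi)) / (hi - mid)
    return fb


def _deltas(c: np.ndarray, width: int = 2) -> np.ndarray:
    """+-`width`-frame regression deltas with edge replication."""
    T = c.shape[0]
    pad = np.pad(c, ((width, width), (0, 0)), mode="edge")
    denom = 2.0 * sum(n * n for n in range(1, width + 1))
    out = np.zeros_like(c)
    for n in range(1, width + 1):
        out += n * (pad[width + n:width + n + T] - pad[width - n:width - n + T])
    return out / denom


def mfcc_sum_features(rec: StereoRecording, cfg: FeatureConfig) -> np.ndarray:
    """39-d MFCC block of the channel mean: [12 MFCC + RMS, delta, delta-delta]."""
    mono = rec.samples.mean(axis=0)
    if cfg.pre_emphasis > 0:
        mono = np.append(mono[0], mono[1:] - cfg.pre_emphasis * mono[:-1])
    frames = frame_signal(mono, cfg.win, cfg.hop, rec.rate)
    rms = np.sqrt((frames ** 2).mean(axis=1))

    n_win = frames.shape[1]
    if cfg.fft_size < n_win:
        raise ValueError("fft_size must cover the analysis window")
    windowed = frames * np.hamming(n_win)[None, :]
    spec = np.abs(rfft(windowed, n=cfg.fft_size, axis=1)) ** 2
    fb = _mel_filterbank(cfg.n_mel, cfg.fft_size, rec.rate)
    mel = np.log(np.maximum(spec @ fb.T, 1e-10))
    ceps = dct(mel, type=2, norm="ortho", axis=1)[:, 1:cfg.n_mfcc + 1]

    static = np.column_stack([ceps, rms])
    d = _deltas(static)
    dd = _deltas(d)
    return np.column_stack([static, d, dd])


def cross_correlation_features(rec: StereoRecording, cfg: FeatureConfig) -> np.ndarray:
    """Per-frame normalized cross-correlation at small integer sample lags.

    r(lag) = sum_n l[n] * r[n+lag] / sqrt(sum l^2 * sum r^2), clipped to
    [-1, 1]; zero-energy frames yield all-zero rows.
    """
    lf = frame_signal(rec.samples[0], cfg.win, cfg.hop, rec.rate)
    rf = frame_signal(rec.samples[1], cfg.win, cfg.hop, rec.rate)
    half = (cfg.cc_points - 1) // 2
    T, N = lf.shape
    out = np.zeros((T, cfg.cc_points))
    energy = np.sqrt((lf ** 2).sum(axis=1) * (rf ** 2).sum(axis=1))
    ok = energy > 0
    for j, lag in enumerate(range(-half, half + 1)):
        if lag >= 0:
            num = (lf[:, :N - lag] * rf[:, lag:]).sum(axis=1) if lag < N else 0.0
        else:
            num = (lf[:, -lag:] * rf[:, :N + lag]).sum(axis=1)
        out[ok, j] = num[ok] / energy[ok] if np.ndim(num) else 0.0
    return np.clip(out, -1.0, 1.0)


def extract_features(rec: StereoRecording, cfg: Optional[FeatureConfig] = None) -> FeatureMatrix:
    """T x (39 + cc_points) feature matrix: [MFCC block | cross-correlation]."""
    cfg = cfg or FeatureConfig()
    mf = mfcc_sum_features(rec, cfg)
    cc = cross_correlation_features(rec, cfg)
    values = np.column_stack([mf, cc])
    times = cfg.hop * np.arange(values.shape[0])
    return FeatureMatrix(values=values, frame_times=times, rate=rec.rate)


def save_features(path: str, fm: FeatureMatrix) -> None:
    """Cache a feature matrix (float32) to an .npz container."""
    np.savez(path, values=fm.values.astype(np.float32),
             frame_times=fm.frame_times, rate=fm.rate)


def load_features(path: str) -> FeatureMatrix:
    z = np.load(path)
    return FeatureMatrix(values=z["values"].astype(np.float64),
                         frame_times=z["frame_times"], rate=int(z["rate"]))
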