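"""Concatenative data augmentation driven by an event-sequence model.

Weak labels are cheap, so their *statistics* can stretch a small corpus: a
5-gram model over chew/bite tokens {L, R, F} captures runs of same-side
chewing, a Normal(mu, sigma) model captures how many chews precede each
swallow, and new recordings are synthesized by sampling an event sequence
from these models and concatenating real event clips from the clip database.
Clip selection favors clips cut from a similar position within their source
recording — weight 1/(|t_i - c| + 1) for a clip cut at t_i when the
generated recording has reached position c — preserving the louder
first-half / quieter second-half structure of a chewing bout.  Models are fit
and applied per (speaker, food) pair; foods with no swallows (chewing gum)
disable the swallow model.
"""

from __future__ import annotations

import os
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .alignment import ClipDB
from .io import (DatasetManifest, IntervalAnnotation, ManifestRow, Segment,
                 StereoRecording, WeakLabelSequence, read_weak_labels,
                 write_intervals, write_manifest, write_wav, write_weak_labels)

__all__ = ["NGramModel", "SwallowCountModel", "AugmentConfig", "fit_ngram",
           "fit_swallow_model", "generate_event_sequence", "selection_weights",
           "synthesize_recording", "augment_dataset"]

CHEW_TOKENS = ("L", "R", "F")   # the n-gram alphabet: no S, no O
_PAD = "<s>"


class NGramModel:
    """Backoff n-gram over {L, R, F} with maximum-likelihood conditionals.

    Counts are kept for every order 1..n; an unseen context backs off to the
    next shorter context, bottoming out in an add-one-smoothed unigram, so
    every conditional distribution sums to 1.
    """

    def __init__(self, order: int = 5):
        if order < 1:
            raise ValueError("order must be >= 1")
        self.order = order
        # counts[k][context tuple of length k] = Counter over next token
        self.counts: List[Dict[tuple, Counter]] = [defaultdict(Counter)
                                                   for _ in range(order)]

    def fit(self, sequences: Iterable[Sequence[str]]) -> "NGramModel":
        n_seq = 0
        for seq in sequences:
            tokens = [t for t in seq if t in CHEW_TOKENS]   # S removed
            if not tokens:
                continue
            n_seq += 1
            padded = [_PAD] * (self.order - 1) + tokens
            for i in range(self.order - 1, len(padded)):
                for k in range(self.order):
                    ctx = tuple(padded[i - k:i])
                    self.counts[k][ctx][padded[i]] += 1
        if n_seq == 0:
            raise ValueError("empty corpus: no chew/bite tokens to fit")
        return self

    def probs(self, context: Sequence[str]) -> Dict[str, float]:
        """Conditional distribution over {L, R, F} given the context tail."""
        ctx = ([_PAD] * (self.order - 1) + list(context))[len(context):] \
            if len(context) < self.order - 1 else list(context)
        ctx = ctx[-(self.order - 1):] if self.order > 1 else []
        for k in range(len(ctx), -1, -1):
            key = tuple(ctx[len(ctx) - k:])
            counter = self.counts[k].get(key)
            if counter:
                total = sum(counter.values())
                return {t: counter.get(t, 0) / total for t in CHEW_TOKENS}
        # add-one unigram floor (empty corpus is rejected in fit)
        uni = self.counts[0].get((), Counter())
        total = sum(uni.values()) + len(CHEW_TOKENS)
        return {t: (uni.get(t, 0) + 1) / total for t in CHEW_TOKENS}

    def sample(self, context: Sequence[str], rng: np.random.Generator) -> str:
        p = self.probs(context)
        return str(rng.choice(CHEW_TOKENS, p=[p[t] for t in CHEW_TOKENS]))


@dataclass
class SwallowCountModel:
    """Normal model of chew/bite tokens per swallow; disabled when no S seen."""

    mu: float = 0.0
    sigma: float = 0.0
    enabled: bool = True

    def __post_init__(self):
        if self.enabled and self.mu <= 0:
            raise ValueError("mu must be positive when enabled")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")

    def draw(self, rng: np.random.Generator) -> int:
        """Chews until the next swallow: round(Normal(mu, sigma)), min 1."""
        return max(1, int(round(rng.normal(self.mu, self.sigma))))


@dataclass
class AugmentConfig:
    multiplier: int = 10
    seed: int = 0
    per_speaker_per_food: bool = True
    ngram_order: int = 5
    length_jitter: float = 0.2   # generated length = mean original +-20%

    def __post_init__(self):
        if self.multiplier < 1:
            raise ValueError("multiplier must be >= 1")


def fit_ngram(sequences: Iterable[Sequence[str]], order: int = 5) -> NGramModel:
    """Maximum-likelihood backoff n-gram over chew/bite tokens (S removed)."""
    seqs = [list(s.tokens) if isinstance(s, WeakLabelSequence) else list(s)
            for s in sequences]
    if not seqs:
        raise ValueError("empty corpus")
    return NGramModel(order=order).fit(seqs)


def fit_swallow_model(sequences: Iterable[Sequence[str]]) -> SwallowCountModel:
    """mu/sigma of chew+bite counts between bout start (or previous S) and S."""
    counts = []
    for seq in sequences:
        tokens = list(seq.tokens) if isinstance(seq, WeakLabelSequence) else list(seq)
        run = 0
        for t in tokens:
            if t == "S":
                counts.append(run)
                run = 0
            elif t in CHEW_TOKENS:
                run += 1
    if not counts:
        return SwallowCountModel(mu=0.0, sigma=0.0, enabled=False)
    return SwallowCountModel(mu=float(np.mean(counts)),
                             sigma=float(np.std(counts)), enabled=True)


def generate_event_sequence(ngram: NGramModel, swallow: SwallowCountModel,
                            target_events: int, rng: np.random.Generator,
                            speaker: str = "", food: str = "") -> WeakLabelSequence:
    """Sample a weak label sequence of `target_events` tokens.

    Chew/bite tokens come from the n-gram; when the swallow model is enabled
    an S is emitted after every K chew/bite tokens with K redrawn from
    round(Normal(mu, sigma)) clipped to >= 1.
    """
    if target_events < 1:
        raise ValueError("target_events must be >= 1")
    tokens: List[str] = []
    context: List[str] = []
    k = swallow.draw(rng) if swallow.enabled else None
    since_swallow = 0
    while len(tokens) < target_events:
        if swallow.enabled and since_swallow >= k:
            tokens.append("S")
            since_swallow = 0
            k = swallow.draw(rng)
            continue
        tok = ngram.sample(context, rng)
        tokens.append(tok)
        context.append(tok)
        since_swallow += 1
    return WeakLabelSequence(tokens=tokens, speaker=speaker, food=food)


def selection_weights(candidate_positions: Sequence[float], current: float) -> np.ndarray:
    """Normalized clip-selection probabilities 1/(|t_i - c| + 1).

    A clip cut at the same source position as the current synthesis position
    gets maximal unnormalized weight 1; the absolute distance keeps the rate
    defined for clips on either side of c.
    """
    t = np.asarray(candidate_positions, dtype=np.float64)
    if t.size == 0:
        raise ValueError("empty candidate set")
    w = 1.0 / (np.abs(t - current) + 1.0)
    return w / w.sum()


def synthesize_recording(sequence: WeakLabelSequence, clipdb: ClipDB,
                         speaker: str, food: str, rng: np.random.Generator
                         ) -> Tuple[StereoRecording, WeakLabelSequence, IntervalAnnotation]:
    """Concatenate clips for an event sequence into a new weak-labeled recording.

    For each token a clip is drawn from the (speaker, food, token) pool with
    probability proportional to 1/(|t_i - c| + 1), where c is the current
    synthesis position; c advances by each appended clip's duration.  The
    emitted intervals are the exact spans of the concatenated clips.
    """
    chunks = []
    segments = []
    rate = None
    c = 0.0
    for tok in sequence.tokens:
        pool = clipdb.get(speaker, food, tok)
        if not pool:
            raise ValueError(f"no clips for (speaker={speaker!r}, food={food!r}, "
                             f"token={tok!r})")
        w = selection_weights([p.t_i for p in pool], c)
        clip = pool[rng.choice(len(pool), p=w)]
        if rate is None:
            rate = clip.rate
        elif clip.rate != rate:
            raise ValueError("clip database mixes sampling rates")
        chunks.append(clip.waveform)
        segments.append(Segment(c, c + clip.duration, tok))
        c += clip.duration
    rec = StereoRecording(samples=np.concatenate(chunks, axis=1), rate=rate)
    weak = WeakLabelSequence(tokens=list(sequence.tokens), speaker=speaker,
                             food=food)
    # segment times are rational in samples; rebuild from sample counts so the
    # annotation matches the waveform exactly
    exact = []
    pos = 0
    for chunk, seg in zip(chunks, segments):
        n = chunk.shape[1]
        exact.append(Segment(pos / rate, (pos + n) / rate, seg.label))
        pos += n
    return rec, weak, IntervalAnnotation(segments=exact)


def augment_dataset(manifest: DatasetManifest, clipdb: ClipDB,
                    config: Optional[AugmentConfig] = None,
                    out_dir: str = "augmented") -> DatasetManifest:
    """Generate multiplier x (original count) new recordings per (speaker, food).

    N-gram and swallow models are fit from each pair's own weak labels; each
    generated recording's event count is the pair's mean original count with
    +-`length_jitter` uniform jitter.  All randomness derives from
    ``config.seed``; rerunning reproduces identical bytes.
    """
    cfg = config or AugmentConfig()
    os.makedirs(out_dir, exist_ok=True)
    rows_out: List[ManifestRow] = []
    for gi, ((speaker, food), rows) in enumerate(sorted(manifest.groups())):
        weaks = [read_weak_labels(r.weak, speaker=speaker, food=food)
                 for r in rows]
        ngram = fit_ngram(weaks, order=cfg.ngram_order)
        swallow = fit_swallow_model(weaks)
        mean_events = float(np.mean([len(w) for w in weaks]))
        rng = np.random.default_rng([cfg.seed, gi])
        for j in range(cfg.multiplier * len(rows)):
            jitter = rng.uniform(1.0 - cfg.length_jitter, 1.0 + cfg.length_jitter)
            n_events = max(1, int(round(mean_events * jitter)))
            seq = generate_event_sequence(ngram, swallow, n_events, rng,
                                          speaker=speaker, food=food)
            rec, weak, ann = synthesize_recording(seq, clipdb, speaker, food, rng)
            stem = f"aug_{speaker}_{food}_{j:04d}"
            wav = os.path.join(out_dir, stem + ".wav")
            weak_path = os.path.join(out_dir, stem + ".weak.txt")
            strong_path = os.path.join(out_dir, stem + ".intervals.tsv")
            write_wav(wav, rec)
            write_weak_labels(weak_path, weak)
            write_intervals(strong_path, ann)
            rows_out.append(ManifestRow(wav=wav, weak=weak_path,
                                        strong=strong_path, speaker=speaker,
                                        food=food))
    out = DatasetManifest(rows=rows_out)
    write_manifest(os.path.join(out_dir, "manifest.csv"), out,
                   relative_to=out_dir)
    return out
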