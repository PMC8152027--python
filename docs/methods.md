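# Methods

This note records the modeling assumptions, parameter choices and numerical
conventions behind `eatsound`, and what the bundled synthetic data does and
does not establish.

## Problem setting

Eating produces a sparse sequence of short acoustic events — front bites,
left/right chews, swallows — separated by silence and noise.  Two under-ear
microphones see each chew asymmetrically: the ipsilateral channel is louder
and *leads* by a fraction of a millisecond (an inter-ear path difference of a
few centimeters is 1–3 samples at 22.05 kHz).  Supervision is weak: per
recording an ordered token list without times.  Timed ("strong") annotations
exist only for evaluation and are never used in training.

## Features

80 ms windows with a 40 ms hop (25 frames/s).  Per frame:

* **MFCC block (39-d)** of the channel *mean* (the mean rather than the raw
  sum avoids clipping while preserving the in-phase chewing signal): 12
  cepstral coefficients (c1–c12 of a 26-filter mel bank, 0 Hz–Nyquist, FFT
  2048, Hamming window) plus frame RMS, with ±2-frame regression Δ and ΔΔ
  appended (edge frames replicated).  No pre-emphasis by default — the
  signals are body-conducted and low-frequency-heavy; a config flag exposes
  it.
* **Cross-correlation (k-d, default k = 7)**: normalized cross-correlation
  of the raw left/right frames at integer sample lags −(k−1)/2 … +(k−1)/2.
  Sign convention: positive lag means the right channel's content arrives
  later, so left-side events peak at positive lags.  Zero-energy frames get
  all-zero rows; values are clipped to [−1, 1].  Raw-sample correlation (not
  an envelope) is used; at these tiny lags the waveform itself carries the
  timing cue.

## Model

* **Encoder**: 2 bidirectional GRU layers, hidden size 48 per direction, no
  temporal subsampling (at 25 frames/s the sequences are short).  The size
  is deliberately small: every forward/backward pass runs in pure numpy on
  one CPU, and on the separable synthetic task larger encoders only slow
  training without changing the measured contrasts.
* **CTC head**: 5-way softmax `{blank, L, R, F, S}`.  The blank doubles as
  the "others" frame class (silence/noise), so frame-level output needs no
  separate garbage class.
* **Attention decoder**: GRU (hidden 48) over the 6-symbol vocabulary
  `{sos, eos, L, R, F, S}`; additive (content-based) attention; the context
  vector is concatenated with the decoder state for the output projection.
  Location-aware attention was left out as out of scope.
* **Loss**: `α·L_CTC + (1−α)·L_att`, α = 0.7 by default; α = 1 and α = 0
  degenerate to the pure CTC and pure attention models and are supported
  (the CTC head of an α = 0 model is untrained and its frame posteriors are
  meaningless — expected, and visible in its MAPE).
* **Training**: Adam (lr 1e-3), gradient-norm clipping at 5, batches of 16
  bucketed by length, 12 epochs by default, fully seeded.  The CTC term is
  averaged per sequence and the attention term per token; mixing a
  per-sequence with a per-token average keeps both gradients at usable scale
  for short event sequences.
* **Decoding**: beam search (width 5) over decoder symbols scoring
  `α·(CTC prefix log-probability) + (1−α)·(attention log-probability)`; a
  hypothesis ends by eos using the full-sequence CTC probability.
  Hypothesis length is capped at the frame count.  CTC prefix probabilities
  follow the standard incremental non-blank/blank recursion.

The CTC loss is computed by the log-space forward recursion with an analytic
forward–backward gradient; it is checked against explicit path enumeration
to 1e-8 in the test suite (float64 throughout).

## Forced alignment and the clip database

Alignment is the Viterbi best path through the CTC trellis constrained to
the weak label sequence; trellis ties prefer staying in the current state,
making alignments deterministic.  Best-path (rather than posterior-argmax)
alignment keeps the emitted path consistent with the collapse rule by
construction.  Clips run from one event's start frame to the next event's
start (the last to the recording end), so the cuts partition the recording
sample-exactly; audio before the first event is "others" and is discarded.
A CTC-trained bootstrap model (α = 1) is the intended aligner, but any
checkpoint with a CTC head is accepted.

## Augmentation

Per (speaker, food) pair: a backoff 5-gram over `{L, R, F}` (S removed
before counting; maximum-likelihood conditionals; unseen contexts back off
to shorter contexts, bottoming in an add-one unigram) and a Normal(μ, σ)
model of chew/bite counts between swallows (F counts toward the total, since
a bite is oral processing preceding the chews of a bout).  Generated
swallow counts are `round(N(μ, σ))` clipped to ≥1 — a non-positive event
count is meaningless.  Foods without swallows (chewing gum) disable the
swallow model and generated sequences contain no S.

Clip selection uses weight `1/(|tᵢ−c|+1)` for a clip cut at position `tᵢ` of
its source recording when the synthesized recording has reached position
`c`.  The absolute value is a deliberate reading: the raw rate `1/(tᵢ−c+1)`
is negative or undefined for clips earlier than `c`, while absolute distance
preserves the intent — prefer clips from a similar point in the bout, which
keeps the louder-first-half structure.  Clips are concatenated without
crossfade; each clip already extends to the next event's onset, so junctions
fall at event boundaries.  Generated recording length is drawn as the
pair's mean original event count ±20%.

## Smoothing and evaluation

Double threshold with defaults φ_high = 0.5, φ_low = 0.2 (both exposed):
frames above φ_high seed a detection, extended through contiguous frames
above φ_low, applied to the four event tracks only; a frame active for
several classes takes the highest posterior, a frame active for none is O.

Frame view: MAPE over (recording, class) entries with a positive reference
frame count; zero-reference entries are excluded and logged.  Reference
frames come from discretizing intervals with a *strict-majority* rule — a
frame takes a class only if that class overlaps more than half the window,
ties to the earlier-starting segment, else O — which makes frame labels
insensitive to grazing overlaps (a 1 ns guard keeps exactly-half overlaps at
O regardless of float rounding).  Estimated frames are the smoothed
(double-thresholded) classes.  Event view: any temporal overlap of
same-class events counts as a detection; recall is reference-side, precision
estimate-side; F1 is the harmonic mean with 0/0 → 0.  The 3-class collapse
maps `{L,R,F} → chewing` (a front bite is oral processing; dropping it would
silently deflate chewing recall), `S → swallowing`, `O → others`.
Time-normalized reports split each bout (start of eating or previous swallow
→ next swallow) into five equal half-open bins, assigning events by start
time, boundary events to the later bin.

## Synthetic generator

The generator emulates the structure the detector and augmenter rely on:
chews are 60–150 ms bursts of 500–4000 Hz noise with exponential decay,
bites 30–80 ms broadband clicks, swallows 200–400 ms 50–500 Hz bursts; side
events get +6 dB ipsilateral gain and a 2-sample contralateral delay; sides
persist with probability 0.8; swallows arrive after `round(N(12, 3))` chews;
amplitude decays ×0.97 per event within a bout and resets after a swallow;
events are separated by 0.12–0.35 s of silence under background noise at
20 dB SNR.  Speakers differ by seeded jitter of gain, tempo and chew band.
Labels are exact by construction.

What it does **not** model: bone-conduction transfer functions, food-specific
spectra, speech/ambient interference, label noise in self-reported weak
labels, or room acoustics.  Passing the end-to-end checks therefore shows
that the pipeline's machinery is correct and that the hybrid objective and
features behave as designed on data with the assumed structure — not that
the measured F1/MAPE transfer to real recordings.

## Problem sizes

The end-to-end checks train on 300 recordings (5 speakers × 60, 8–16 events
each) and score 60 held-out recordings from 5 unseen-seed speakers; the
statistical checks use 50 000 generated tokens (n-gram recovery), 1000
swallow gaps, and 10⁴ selection draws.  These sizes put every quantity's
sampling error well inside its tolerance while keeping a full run in minutes
on one CPU.

## Known limitations

* Pure numpy training limits practical model size; real-data scale would
  warrant a GPU framework with the same architecture.
* Front biting is the weakest class end to end (very short, broadband,
  rare), mirroring its difficulty in real data; the event decoder finds it
  far more reliably than the frame track does.
* CTC frame posteriors tend to sharpen around event onsets with long
  training; the double threshold compensates only down to φ_low.  Frame
  counts are therefore systematically conservative.
* The n-gram treats the token stream per (speaker, food); cross-speaker or
  cross-food pooling is deliberately not supported (clip timbre differs).
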