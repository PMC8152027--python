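"""Hybrid CTC/attention sequence model for eating-event detection.

The detector maps a frame-level acoustic feature sequence to an ordered list
of eating events (L/R chewing, F biting, S swallowing) using only weak labels
for supervision.  A bidirectional GRU encoder feeds two heads:

* a CTC head — per-frame softmax over {blank, L, R, F, S}, trained with the
  CTC marginal likelihood so no frame-level alignment is needed (blank doubles
  as the "others" frame class: silence and noise);
* an attention decoder — an autoregressive GRU with additive (content-based)
  attention over encoder states, which models event *context* (runs of
  same-side chews, swallows closing a bout).

Training minimizes ``alpha * L_ctc + (1 - alpha) * L_att``; decoding is a
joint beam search scoring hypotheses by ``alpha`` times the CTC prefix
log-probability plus ``1 - alpha`` times the attention log-probability.
"""

from __future__ import annotations

import io as _stdio
import json
import warnings
from dataclasses import dataclass, asdict, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .autodiff import Adam, Tensor, concat, constant, parameter, stack
from .features import FeatureConfig, FeatureMatrix, extract_features
from .io import DatasetManifest, WeakLabelSequence, read_wav, read_weak_labels

__all__ = [
    "Vocab", "ModelConfig", "PosteriorTrack", "ctc_loss", "ctc_nll",
    "ctc_feasible", "hybrid_loss", "teacher_forced_nll", "HybridModel",
    "frame_posteriors", "decode_joint", "train",
]

NEG_INF = -np.inf


class Vocab:
    """Symbol tables: CTC {blank,L,R,F,S}; decoder {sos,eos,L,R,F,S}."""

    BLANK = 0
    CTC_SYMBOLS = ("O", "L", "R", "F", "S")     # index 0 is blank/others
    CTC_ID = {"L": 1, "R": 2, "F": 3, "S": 4}
    SOS = 0
    EOS = 1
    DEC_SYMBOLS = ("<sos>", "<eos>", "L", "R", "F", "S")
    DEC_ID = {"L": 2, "R": 3, "F": 4, "S": 5}
    N_CTC = 5
    N_DEC = 6


@dataclass
class ModelConfig:
    enc_layers: int = 2
    enc_hidden: int = 48
    bidirectional: bool = True
    dec_hidden: int = 48
    att_dim: int = 48
    alpha: float = 0.7          # hybrid weight on the CTC loss
    seed: int = 0
    lr: float = 1e-3
    epochs: int = 12
    batch_size: int = 16
    clip_norm: float = 5.0
    beam: int = 5

    def __post_init__(self):
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError("alpha must lie in [0, 1]")
        for name in ("enc_layers", "enc_hidden", "dec_hidden", "att_dim"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


@dataclass
class PosteriorTrack:
    """T x 5 frame probabilities over (O/blank, L, R, F, S)."""

    probs: np.ndarray

    def __post_init__(self):
        p = np.asarray(self.probs, dtype=np.float64)
        if p.ndim != 2 or p.shape[1] != Vocab.N_CTC:
            raise ValueError("posterior track must be T x 5")
        if np.any(p < -1e-9) or np.any(p > 1 + 1e-9):
            raise ValueError("posterior entries must lie in [0, 1]")
        if not np.allclose(p.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("posterior rows must sum to 1")
        self.probs = p

    @property
    def n_frames(self) -> int:
        return self.probs.shape[0]


# ---------------------------------------------------------------------------
# CTC loss (log-space forward-backward with an analytic gradient)
# ---------------------------------------------------------------------------

def _as_ctc_ids(target) -> List[int]:
    if isinstance(target, WeakLabelSequence):
        target = target.tokens
    ids = []
    for t in target:
        if isinstance(t, str):
            if t not in Vocab.CTC_ID:
                raise ValueError(f"invalid target token {t!r}")
            ids.append(Vocab.CTC_ID[t])
        else:
            ids.append(int(t))
    if any(i < 1 or i >= Vocab.N_CTC for i in ids):
        raise ValueError("target ids must be label (non-blank) symbols")
    return ids


def ctc_feasible(n_frames: int, target) -> bool:
    ids = _as_ctc_ids(target)
    repeats = sum(1 for a, b in zip(ids, ids[1:]) if a == b)
    return n_frames >= len(ids) + repeats


def _extended(ids: List[int]) -> np.ndarray:
    ext = [Vocab.BLANK]
    for i in ids:
        ext.extend((i, Vocab.BLANK))
    return np.asarray(ext, dtype=np.int64)


def ctc_nll(log_probs: Tensor, target) -> Tensor:
    """-ln p(target | x) under CTC, differentiable w.r.t. `log_probs` (T x K).

    p(target|x) marginalizes over every frame path that collapses to the
    target (blanks and adjacent repeats removed); repeated adjacent target
    labels require an intervening blank.  Computed by the log-space forward
    recursion; the backward pass uses forward-backward occupancies.
    """
    ids = _as_ctc_ids(target)
    lp = log_probs.data
    T = lp.shape[0]
    if not ctc_feasible(T, ids):
        raise ValueError(
            f"infeasible CTC target: length {len(ids)} (+repeats) needs more "
            f"than {T} frames")
    ext = _extended(ids)
    S = len(ext)
    skip = np.zeros(S, dtype=bool)
    skip[2:] = (ext[2:] != Vocab.BLANK) & (ext[2:] != ext[:-2])

    alpha = np.full((T, S), NEG_INF)
    alpha[0, 0] = lp[0, ext[0]]
    if S > 1:
        alpha[0, 1] = lp[0, ext[1]]
    for t in range(1, T):
        prev = alpha[t - 1]
        m = prev.copy()
        m[1:] = np.logaddexp(m[1:], prev[:-1])
        m[2:] = np.where(skip[2:], np.logaddexp(m[2:], prev[:-2]), m[2:])
        alpha[t] = m + lp[t, ext]

    logp = alpha[T - 1, S - 1]
    if S > 1:
        logp = np.logaddexp(logp, alpha[T - 1, S - 2])
    if not np.isfinite(logp):
        raise ValueError("target has zero probability under the posteriors")

    beta = np.full((T, S), NEG_INF)
    beta[T - 1, S - 1] = 0.0
    if S > 1:
        beta[T - 1, S - 2] = 0.0
    for t in range(T - 2, -1, -1):
        nxt = beta[t + 1] + lp[t + 1, ext]
        m = nxt.copy()
        m[:-1] = np.logaddexp(m[:-1], nxt[1:])
        m[:-2] = np.where(skip[2:], np.logaddexp(m[:-2], nxt[2:]), m[:-2])
        beta[t] = m

    with np.errstate(invalid="ignore"):
        occ = np.exp(alpha + beta - logp)        # (T, S) state occupancies
    occ[~np.isfinite(occ)] = 0.0
    dlp = np.zeros_like(lp)
    for s in range(S):
        dlp[:, ext[s]] -= occ[:, s]

    out = Tensor(np.float64(-logp), log_probs.requires_grad, (log_probs,))

    def bw(g):
        if log_probs.requires_grad:
            log_probs._acc(g * dlp)
    out._bw = bw
    return out


def ctc_loss(log_posteriors: np.ndarray, target) -> float:
    """Convenience wrapper: -ln p(target|x) from a plain (T x K) log array."""
    return ctc_nll(constant(np.asarray(log_posteriors, dtype=np.float64)),
                   target).item()


def hybrid_loss(l_ctc: float, l_att: float, alpha: float) -> float:
    """Weighted linear sum ``alpha * l_ctc + (1 - alpha) * l_att``."""
    if not (0.0 <= alpha <= 1.0):
        raise ValueError("alpha must lie in [0, 1]")
    return alpha * l_ctc + (1.0 - alpha) * l_att


def teacher_forced_nll(step_log_probs: np.ndarray, target) -> float:
    """Mean negative log-likelihood of target tokens + eos.

    `step_log_probs` holds the decoder's per-step log-probabilities over the
    6-symbol decoder vocabulary, one row per target token plus a final row
    for eos.
    """
    if isinstance(target, WeakLabelSequence):
        target = target.tokens
    if len(target) == 0:
        raise ValueError("empty target")
    ids = [Vocab.DEC_ID[t] if isinstance(t, str) else int(t) for t in target]
    ids.append(Vocab.EOS)
    lp = np.asarray(step_log_probs, dtype=np.float64)
    if lp.shape[0] != len(ids):
        raise ValueError("need one decoder step per token plus one for eos")
    return float(-lp[np.arange(len(ids)), ids].mean())


# ---------------------------------------------------------------------------
# the network
# ---------------------------------------------------------------------------

def _glorot(rng, fan_in, fan_out, shape=None):
    lim = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-lim, lim, size=shape or (fan_in, fan_out))


class HybridModel:
    """Bidirectional GRU encoder + CTC head + attention GRU decoder."""

    def __init__(self, input_dim: int, config: Optional[ModelConfig] = None):
        self.input_dim = int(input_dim)
        self.config = config or ModelConfig()
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        H, Hd, A = cfg.enc_hidden, cfg.dec_hidden, cfg.att_dim
        self.n_dirs = 2 if cfg.bidirectional else 1
        self.enc_out = H * self.n_dirs
        P = {}
        for layer in range(cfg.enc_layers):
            d_in = self.input_dim if layer == 0 else self.enc_out
            for d in range(self.n_dirs):
                P[f"enc{layer}d{d}_Wx"] = parameter(_glorot(rng, d_in, 3 * H))
                P[f"enc{layer}d{d}_Wh"] = parameter(_glorot(rng, H, 3 * H))
                P[f"enc{layer}d{d}_b"] = parameter(np.zeros(3 * H))
        P["ctc_W"] = parameter(_glorot(rng, self.enc_out, Vocab.N_CTC))
        P["ctc_b"] = parameter(np.zeros(Vocab.N_CTC))
        d_dec_in = Vocab.N_DEC + self.enc_out
        P["dec_Wx"] = parameter(_glorot(rng, d_dec_in, 3 * Hd))
        P["dec_Wh"] = parameter(_glorot(rng, Hd, 3 * Hd))
        P["dec_b"] = parameter(np.zeros(3 * Hd))
        P["att_W"] = parameter(_glorot(rng, Hd, A))
        P["att_U"] = parameter(_glorot(rng, self.enc_out, A))
        P["att_b"] = parameter(np.zeros(A))
        P["att_v"] = parameter(_glorot(rng, A, 1))
        P["out_W"] = parameter(_glorot(rng, Hd + self.enc_out, Vocab.N_DEC))
        P["out_b"] = parameter(np.zeros(Vocab.N_DEC))
        self.params = P

    # -- encoder ----------------------------------------------------------
    def _gru_step(self, xp: Tensor, h: Tensor, Wh: Tensor, H: int) -> Tensor:
        hp = h @ Wh
        z = (xp[:, 0:H] + hp[:, 0:H]).sigmoid()
        r = (xp[:, H:2 * H] + hp[:, H:2 * H]).sigmoid()
        n = (xp[:, 2 * H:3 * H] + r * hp[:, 2 * H:3 * H]).tanh()
        return z * h + (1.0 - z) * n

    def encode(self, X: np.ndarray, mask: Optional[np.ndarray] = None) -> Tensor:
        """Run the encoder over a padded batch.

        X: (B, T, D) features; mask: (B, T) with 1 on valid frames.  Returns
        encoder states as a (B, T, n_dirs*H) tensor; padded steps hold zeros
        carried through the masked update.
        """
        cfg = self.config
        B, T, _ = X.shape
        if mask is None:
            mask = np.ones((B, T))
        inp = constant(X)
        H = cfg.enc_hidden
        for layer in range(cfg.enc_layers):
            d_in = inp.shape[2]
            dir_outs = []
            for d in range(self.n_dirs):
                Wx = self.params[f"enc{layer}d{d}_Wx"]
                Wh = self.params[f"enc{layer}d{d}_Wh"]
                b = self.params[f"enc{layer}d{d}_b"]
                proj = (inp.reshape(B * T, d_in) @ Wx + b).reshape(B, T, 3 * H)
                h = constant(np.zeros((B, H)))
                hs: List[Optional[Tensor]] = [None] * T
                order = range(T) if d == 0 else range(T - 1, -1, -1)
                for t in order:
                    xp = proj[:, t, :]
                    h_new = self._gru_step(xp, h, Wh, H)
                    m = mask[:, t:t + 1]
                    h = h + (h_new - h) * m if m.min() < 1 else h_new
                    hs[t] = h
                dir_outs.append(stack(hs, axis=1))      # (B, T, H)
            inp = concat(dir_outs, axis=2) if self.n_dirs == 2 else dir_outs[0]
        return inp

    def ctc_log_probs(self, enc: Tensor) -> Tensor:
        """(B, T, 5) log-softmax of the CTC head."""
        B, T, E = enc.shape
        logits = enc.reshape(B * T, E) @ self.params["ctc_W"] + self.params["ctc_b"]
        return logits.reshape(B, T, Vocab.N_CTC).log_softmax(axis=-1)

    # -- attention decoder ------------------------------------------------
    def _decoder_graph(self, enc: Tensor, mask: np.ndarray,
                       targets: List[List[int]],
                       return_attention: bool = False):
        """Teacher-forced decoder over a padded batch.

        targets: per-sequence decoder-vocabulary ids (no sos/eos).  Returns
        (total negative log-likelihood Tensor, token count) — the NLL sums
        over all target tokens plus one eos per sequence.
        """
        cfg = self.config
        B, T, E = enc.shape
        Hd, A = cfg.dec_hidden, cfg.att_dim
        U = max(len(t) for t in targets)
        Y = np.full((B, U + 1), Vocab.EOS, dtype=np.int64)
        valid = np.zeros((B, U + 1))
        for b, t in enumerate(targets):
            Y[b, :len(t)] = t
            valid[b, :len(t) + 1] = 1.0           # tokens + eos
        y_in = np.full((B,), Vocab.SOS, dtype=np.int64)

        UaH = (enc.reshape(B * T, E) @ self.params["att_U"]).reshape(B, T, A)
        att_bias = np.where(mask > 0, 0.0, -1e30)   # (B, T)
        q = constant(np.zeros((B, Hd)))
        nll = constant(np.float64(0.0))
        att_all = []
        for u in range(U + 1):
            wq = (q @ self.params["att_W"] + self.params["att_b"]).reshape(B, 1, A)
            e = ((UaH + wq).tanh().reshape(B * T, A) @ self.params["att_v"])
            e = e.reshape(B, T) + att_bias
            a = e.log_softmax(axis=1).exp()          # (B, T) attention weights
            ctx = (a.reshape(B, 1, T) @ enc).reshape(B, E)
            onehot = np.zeros((B, Vocab.N_DEC))
            onehot[np.arange(B), y_in] = 1.0
            xin = concat([constant(onehot), ctx], axis=1)
            xp = xin @ self.params["dec_Wx"] + self.params["dec_b"]
            q = self._gru_step(xp, q, self.params["dec_Wh"], Hd)
            logits = concat([q, ctx], axis=1) @ self.params["out_W"] + self.params["out_b"]
            lp = logits.log_softmax(axis=-1)
            picked = lp[np.arange(B), Y[:, u]]
            nll = nll + (-(picked * valid[:, u]).sum())
            y_in = Y[:, u]
            if return_attention:
                att_all.append(a.data)
        n_tokens = int(valid.sum())
        if return_attention:
            return nll, n_tokens, np.stack(att_all, axis=1)
        return nll, n_tokens

    def attention_loss(self, enc_states: np.ndarray, target) -> float:
        """Teacher-forced NLL of target + eos, averaged per token."""
        if isinstance(target, WeakLabelSequence):
            target = target.tokens
        if len(target) == 0:
            raise ValueError("empty target")
        ids = [Vocab.DEC_ID[t] if isinstance(t, str) else int(t) for t in target]
        enc = constant(np.asarray(enc_states)[None, :, :])
        mask = np.ones((1, enc.shape[1]))
        nll, n_tokens = self._decoder_graph(enc, mask, [ids])
        return nll.item() / n_tokens

    def attention_weights(self, enc_states: np.ndarray, target) -> np.ndarray:
        """Per-step attention distributions (steps x frames), for inspection."""
        ids = [Vocab.DEC_ID[t] if isinstance(t, str) else int(t) for t in target]
        enc = constant(np.asarray(enc_states)[None, :, :])
        mask = np.ones((1, enc.shape[1]))
        _, _, att = self._decoder_graph(enc, mask, [ids], return_attention=True)
        return att[0]

    # -- inference --------------------------------------------------------
    def encode_features(self, features) -> np.ndarray:
        """Encoder states for one recording's features; (T, enc_out)."""
        X = features.values if isinstance(features, FeatureMatrix) else np.asarray(features)
        if X.shape[1] != self.input_dim:
            raise ValueError(
                f"feature width {X.shape[1]} != model input {self.input_dim}")
        return self.encode(X[None, :, :]).data[0]

    def frame_posteriors(self, features) -> PosteriorTrack:
        """Softmax of the CTC head per frame; deterministic."""
        enc = self.encode_features(features)
        lp = self.ctc_log_probs(constant(enc[None, :, :])).data[0]
        return PosteriorTrack(probs=np.exp(lp))

    def _decoder_step_np(self, enc: np.ndarray, q: np.ndarray, y_prev: int
                         ) -> Tuple[np.ndarray, np.ndarray]:
        """One numpy-only decoder step; returns (log-prob vector, new state)."""
        P = {k: v.data for k, v in self.params.items()}
        Hd = self.config.dec_hidden
        e = np.tanh(enc @ P["att_U"] + q @ P["att_W"] + P["att_b"]) @ P["att_v"]
        e = e[:, 0]
        e -= e.max()
        a = np.exp(e)
        a /= a.sum()
        ctx = a @ enc
        onehot = np.zeros(Vocab.N_DEC)
        onehot[y_prev] = 1.0
        xp = np.concatenate([onehot, ctx]) @ P["dec_Wx"] + P["dec_b"]
        hp = q @ P["dec_Wh"]
        z = _sigm(xp[0:Hd] + hp[0:Hd])
        r = _sigm(xp[Hd:2 * Hd] + hp[Hd:2 * Hd])
        n = np.tanh(xp[2 * Hd:] + r * hp[2 * Hd:])
        q_new = z * q + (1 - z) * n
        logits = np.concatenate([q_new, ctx]) @ P["out_W"] + P["out_b"]
        logits -= logits.max()
        lp = logits - np.log(np.exp(logits).sum())
        return lp, q_new

    def decode_joint(self, features, beam: Optional[int] = None,
                     alpha: Optional[float] = None) -> List[str]:
        """Joint CTC/attention beam search; returns event tokens (no sos/eos).

        Hypotheses are scored by ``alpha * CTC prefix log-probability +
        (1 - alpha) * attention log-probability``; ending a hypothesis uses
        the full-sequence CTC probability plus the eos attention score.
        Hypothesis length is capped at the frame count.
        """
        beam = beam if beam is not None else self.config.beam
        alpha = alpha if alpha is not None else self.config.alpha
        if beam < 1:
            raise ValueError("beam width must be >= 1")
        enc = self.encode_features(features)
        lp = self.ctc_log_probs(constant(enc[None, :, :])).data[0]
        T = lp.shape[0]
        scorer = CTCPrefixScorer(lp)
        Hd = self.config.dec_hidden
        hyps = [{
            "tokens": [], "last": None, "ctc": scorer.initial_state(),
            "att": 0.0, "q": np.zeros(Hd), "y": Vocab.SOS,
        }]
        finished: List[Tuple[float, List[str]]] = []
        for _ in range(T + 1):
            cand = []
            for h in hyps:
                att_lp, q_new = self._decoder_step_np(enc, h["q"], h["y"])
                full = scorer.full_score(h["ctc"])
                end_score = (alpha * full +
                             (1 - alpha) * (h["att"] + att_lp[Vocab.EOS]))
                finished.append((end_score, h["tokens"]))
                if len(h["tokens"]) >= T:
                    continue
                for tok, cid in Vocab.CTC_ID.items():
                    psi, state = scorer.score(h["ctc"], h["last"], cid)
                    if psi == NEG_INF:
                        continue
                    att = h["att"] + att_lp[Vocab.DEC_ID[tok]]
                    cand.append((alpha * psi + (1 - alpha) * att, {
                        "tokens": h["tokens"] + [tok], "last": cid,
                        "ctc": state, "att": att, "q": q_new,
                        "y": Vocab.DEC_ID[tok],
                    }))
            if not cand:
                break
            cand.sort(key=lambda c: -c[0])
            hyps = [c[1] for c in cand[:beam]]
        return max(finished, key=lambda f: f[0])[1]

    # -- persistence ------------------------------------------------------
    def save(self, path: str) -> None:
        """Self-describing checkpoint: config JSON + weights in one .npz."""
        arrays = {k: v.data for k, v in self.params.items()}
        meta = json.dumps({"input_dim": self.input_dim,
                           "config": asdict(self.config)})
        np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
                 **arrays)

    @classmethod
    def load(cls, path: str) -> "HybridModel":
        z = np.load(path)
        meta = json.loads(bytes(z["__meta__"]).decode())
        model = cls(meta["input_dim"], ModelConfig(**meta["config"]))
        for k in model.params:
            model.params[k].data = z[k].astype(np.float64)
        return model


def _sigm(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


class CTCPrefixScorer:
    """Incremental CTC prefix probabilities over a (T x K) log-posterior grid.

    For each hypothesis prefix, tracks the log-probability of emitting exactly
    that prefix over frames 0..t with the path ending in a non-blank
    (``r_n``) or blank (``r_b``) state; extension by one label yields the
    prefix score psi = log p(prefix expands to the hypothesis + anything).
    """

    def __init__(self, log_probs: np.ndarray, blank: int = Vocab.BLANK):
        self.lp = np.asarray(log_probs, dtype=np.float64)
        self.blank = blank
        self.T = self.lp.shape[0]

    def initial_state(self):
        r_b = np.cumsum(self.lp[:, self.blank])
        r_n = np.full(self.T, NEG_INF)
        return r_n, r_b

    def full_score(self, state) -> float:
        r_n, r_b = state
        return float(np.logaddexp(r_n[-1], r_b[-1]))

    def score(self, state, last: Optional[int], c: int):
        r_n_prev, r_b_prev = state
        lp, T = self.lp, self.T
        if last is not None and c == last:
            phi = r_b_prev
        else:
            phi = np.logaddexp(r_b_prev, r_n_prev)
        r_n = np.full(T, NEG_INF)
        r_b = np.full(T, NEG_INF)
        r_n[0] = lp[0, c] if last is None else NEG_INF
        psi = r_n[0]
        for t in range(1, T):
            r_n[t] = lp[t, c] + np.logaddexp(r_n[t - 1], phi[t - 1])
            r_b[t] = lp[t, self.blank] + np.logaddexp(r_b[t - 1], r_n[t - 1])
            psi = np.logaddexp(psi, lp[t, c] + phi[t - 1])
        return float(psi), (r_n, r_b)


# ---------------------------------------------------------------------------
# module-level inference helpers (thin wrappers over HybridModel methods)
# ---------------------------------------------------------------------------

def frame_posteriors(model: HybridModel, features) -> PosteriorTrack:
    return model.frame_posteriors(features)


def decode_joint(model: HybridModel, features, beam: Optional[int] = None,
                 alpha: Optional[float] = None) -> List[str]:
    return model.decode_joint(features, beam=beam, alpha=alpha)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _batch_loss(model: HybridModel, X: np.ndarray, mask: np.ndarray,
                lengths: List[int], targets_ctc: List[List[int]],
                targets_dec: List[List[int]], alpha: float):
    """Hybrid loss over one padded batch; returns (loss, ctc, att) Tensors."""
    enc = model.encode(X, mask)
    logp = model.ctc_log_probs(enc)
    B = X.shape[0]
    ctc_total = constant(np.float64(0.0))
    for b in range(B):
        lp_b = logp[b, :lengths[b], :]
        ctc_total = ctc_total + ctc_nll(lp_b, targets_ctc[b])
    ctc_mean = ctc_total * (1.0 / B)
    att_nll, n_tok = model._decoder_graph(enc, mask, targets_dec)
    att_mean = att_nll * (1.0 / n_tok)
    loss = alpha * ctc_mean + (1.0 - alpha) * att_mean
    return loss, ctc_mean, att_mean


def train(manifest: DatasetManifest, feature_config: Optional[FeatureConfig] = None,
          model_config: Optional[ModelConfig] = None, progress: bool = False):
    """Train a hybrid model on weak labels; returns (model, loss history).

    Features are extracted once per recording and cached in memory; batches
    bucket recordings of similar length.  Recordings whose weak label is
    infeasible for their frame count are skipped with a warning naming the
    recording.  The run is fully seeded by ``model_config.seed``.
    """
    fcfg = feature_config or FeatureConfig()
    mcfg = model_config or ModelConfig()
    if len(manifest) == 0:
        raise ValueError("empty manifest")

    items = []
    for row in manifest:
        rec = read_wav(row.wav)
        fm = extract_features(rec, fcfg)
        weak = read_weak_labels(row.weak, speaker=row.speaker, food=row.food)
        if not ctc_feasible(fm.n_frames, weak.tokens):
            warnings.warn(f"skipping {row.wav}: weak label infeasible for "
                          f"{fm.n_frames} frames")
            continue
        ctc_ids = [Vocab.CTC_ID[t] for t in weak.tokens]
        dec_ids = [Vocab.DEC_ID[t] for t in weak.tokens]
        items.append((fm.values, ctc_ids, dec_ids))
    if not items:
        raise ValueError("no feasible training recordings")

    model = HybridModel(items[0][0].shape[1], mcfg)
    opt = Adam(list(model.params.values()), lr=mcfg.lr)
    rng = np.random.default_rng(mcfg.seed + 1)

    order = np.argsort([len(it[0]) for it in items])
    batches = [order[i:i + mcfg.batch_size]
               for i in range(0, len(order), mcfg.batch_size)]

    history = []
    for epoch in range(mcfg.epochs):
        rng.shuffle(batches)
        ep_ctc, ep_att, ep_hyb, n_b = 0.0, 0.0, 0.0, 0
        for batch in batches:
            group = [items[i] for i in batch]
            lengths = [len(g[0]) for g in group]
            Tm = max(lengths)
            B = len(group)
            X = np.zeros((B, Tm, model.input_dim))
            mask = np.zeros((B, Tm))
            for b, g in enumerate(group):
                X[b, :lengths[b]] = g[0]
                mask[b, :lengths[b]] = 1.0
            loss, lc, la = _batch_loss(model, X, mask, lengths,
                                       [g[1] for g in group],
                                       [g[2] for g in group], mcfg.alpha)
            opt.zero_grad()
            loss.backward()
            opt.clip_grad_norm(mcfg.clip_norm)
            opt.step()
            ep_ctc += lc.item()
            ep_att += la.item()
            ep_hyb += loss.item()
            n_b += 1
        history.append({"epoch": epoch, "ctc_loss": ep_ctc / n_b,
                        "attention_loss": ep_att / n_b,
                        "hybrid_loss": ep_hyb / n_b})
        if progress:
            h = history[-1]
            print(f"epoch {epoch}: hybrid {h['hybrid_loss']:.4f} "
                  f"(ctc {h['ctc_loss']:.4f}, att {h['attention_loss']:.4f})")
    return model, history
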