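"""N-gram fitting, swallow spacing, sequence generation, clip selection."""

import os

import numpy as np
import pytest

from eatsound.alignment import ClipDB, EventClip
from eatsound.augment import (AugmentConfig, NGramModel, SwallowCountModel,
                              augment_dataset, fit_ngram, fit_swallow_model,
                              generate_event_sequence, selection_weights,
                              synthesize_recording)
from eatsound.io import WeakLabelSequence, read_weak_labels


class TestNGram:
    def test_bigram_hand_counts(self):
        m = fit_ngram([list("LLLRRR")], order=2)
        p = m.probs(["L"])
        assert p["L"] == pytest.approx(2 / 3)
        assert p["R"] == pytest.approx(1 / 3)
        assert m.probs(["R"])["R"] == pytest.approx(1.0)

    def test_single_token_corpus_backs_off_to_unigram(self):
        m = fit_ngram([["L"]], order=5)
        assert m.probs(["R", "F", "L", "R"])["L"] == pytest.approx(1.0)

    def test_conditionals_sum_to_one(self, rng):
        seqs = [[str(t) for t in rng.choice(list("LRF"), size=30)]
                for _ in range(10)]
        m = fit_ngram(seqs, order=5)
        for ctx in ([], ["L"], ["L", "R"], ["F", "F", "F", "F"]):
            assert sum(m.probs(ctx).values()) == pytest.approx(1.0)

    def test_swallows_removed_before_counting(self):
        m = fit_ngram([list("LSLSL")], order=2)
        # with S removed the corpus is L L L: P(L|L) = 1
        assert m.probs(["L"])["L"] == pytest.approx(1.0)

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            fit_ngram([], order=5)


class TestSwallowModel:
    def test_hand_counts(self):
        m = fit_swallow_model([list("LLSLLS")])
        assert m.mu == pytest.approx(2.0)
        assert m.sigma == pytest.approx(0.0)
        assert m.enabled

    def test_front_bites_count_toward_total(self):
        m = fit_swallow_model([list("FLLLS")])
        assert m.mu == pytest.approx(4.0)

    def test_no_swallows_disables_model(self):
        m = fit_swallow_model([list("LLRRLL")])
        assert not m.enabled

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            SwallowCountModel(mu=0.0, sigma=1.0, enabled=True)


class TestGenerateSequence:
    def _ngram(self):
        return fit_ngram([list("LLLLRRRRF")], order=2)

    def test_degenerate_normal_spaces_exactly(self):
        swallow = SwallowCountModel(mu=3.0, sigma=0.0, enabled=True)
        seq = generate_event_sequence(self._ngram(), swallow, 20,
                                      np.random.default_rng(0))
        chunks = " ".join(seq.tokens).split("S")
        for chunk in chunks[:-1]:
            assert len(chunk.split()) == 3

    def test_disabled_swallow_emits_no_s(self):
        swallow = SwallowCountModel(enabled=False)
        seq = generate_event_sequence(self._ngram(), swallow, 50,
                                      np.random.default_rng(0))
        assert "S" not in seq.tokens
        assert len(seq.tokens) == 50

    def test_same_seed_identical(self):
        swallow = SwallowCountModel(mu=4.0, sigma=1.0, enabled=True)
        a = generate_event_sequence(self._ngram(), swallow, 30,
                                    np.random.default_rng(9))
        b = generate_event_sequence(self._ngram(), swallow, 30,
                                    np.random.default_rng(9))
        assert a.tokens == b.tokens


class TestSelectionWeights:
    def test_single_candidate(self):
        assert selection_weights([3.0], 10.0) == pytest.approx([1.0])

    def test_zero_distance_is_maximal(self):
        w = selection_weights([5.0, 9.0], 5.0)
        assert w[0] > w[1]
        assert w.sum() == pytest.approx(1.0)

    def test_worked_distances(self):
        w = selection_weights([0.0, 1.0, 4.0], 0.0)
        assert w == pytest.approx([0.588, 0.294, 0.118], abs=1e-3)

    def test_empty_candidates_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            selection_weights([], 0.0)


def _toy_clipdb(rng, rate=22050):
    db = ClipDB()
    for tok in "LRFS":
        for k, t_i in enumerate((0.0, 2.0, 60.0)):
            wav = rng.normal(0, 0.1, (2, 200 + 50 * k))
            db.add(EventClip(waveform=wav, token=tok, t_i=t_i, speaker="a",
                             food="cracker", rate=rate))
    return db


class TestSynthesizeRecording:
    def test_duration_and_labels_exact(self, rng):
        db = _toy_clipdb(rng)
        seq = WeakLabelSequence(tokens=list("FLRS"), speaker="a", food="cracker")
        rec, weak, ann = synthesize_recording(seq, db, "a", "cracker",
                                              np.random.default_rng(1))
        assert weak.tokens == seq.tokens
        assert ann.tokens() == seq.tokens
        total = sum(s.end - s.start for s in ann.segments)
        assert rec.duration == pytest.approx(total)
        assert ann.segments[-1].end == pytest.approx(rec.duration)

    def test_missing_class_rejected(self, rng):
        db = ClipDB()
        db.add(EventClip(waveform=rng.normal(0, 0.1, (2, 100)), token="L",
                         t_i=0.0, speaker="a", food="cracker"))
        seq = WeakLabelSequence(tokens=["S"], speaker="a", food="cracker")
        with pytest.raises(ValueError, match="no clips"):
            synthesize_recording(seq, db, "a", "cracker",
                                 np.random.default_rng(0))

    def test_near_clip_preferred_empirically(self, rng):
        # candidates at t_i = 0 and 60 s with c = 0: odds 1 : 1/61
        db = ClipDB()
        for t_i in (0.0, 60.0):
            db.add(EventClip(waveform=np.full((2, int(100 + t_i)), 0.01),
                             token="L", t_i=t_i, speaker="a", food="x"))
        seq = WeakLabelSequence(tokens=["L"], speaker="a", food="x")
        gen = np.random.default_rng(11)
        near = 0
        n = 10_000
        for _ in range(n):
            rec, _, _ = synthesize_recording(seq, db, "a", "x", gen)
            near += rec.n_samples == 100
        assert near / n == pytest.approx(61 / 62, abs=0.02)


class TestAugmentDataset:
    def test_multiplier_scales_output_count(self, tmp_path, tiny_dataset, rng):
        rows = tiny_dataset.rows[:3]
        manifest = type(tiny_dataset)(rows=rows)
        db = ClipDB()
        weak_seqs = [read_weak_labels(r.weak) for r in rows]
        toks = {t for w in weak_seqs for t in w.tokens}
        for tok in toks:
            for t_i in (0.0, 1.0):
                db.add(EventClip(waveform=rng.normal(0, 0.05, (2, 300)),
                                 token=tok, t_i=t_i, speaker=rows[0].speaker,
                                 food=rows[0].food))
        cfg = AugmentConfig(multiplier=3, seed=0)
        out = augment_dataset(manifest, db, cfg,
                              out_dir=str(tmp_path / "aug"))
        assert len(out) == 3 * len(rows)
        for r in out:
            assert os.path.exists(r.wav)
            assert read_weak_labels(r.weak).tokens  # non-empty

    def test_rerun_reproduces_identical_bytes(self, tmp_path, tiny_dataset, rng):
        rows = tiny_dataset.rows[:2]
        manifest = type(tiny_dataset)(rows=rows)
        db = _toy_clipdb(rng)
        # relabel clips to the manifest's (speaker, food)
        db2 = ClipDB()
        for key in db.keys():
            for c in db.get(*key):
                db2.add(EventClip(waveform=c.waveform, token=c.token,
                                  t_i=c.t_i, speaker=rows[0].speaker,
                                  food=rows[0].food))
        cfg = AugmentConfig(multiplier=1, seed=4)
        out1 = augment_dataset(manifest, db2, cfg, out_dir=str(tmp_path / "a"))
        out2 = augment_dataset(manifest, db2, cfg, out_dir=str(tmp_path / "b"))
        for r1, r2 in zip(out1, out2):
            with open(r1.wav, "rb") as f1, open(r2.wav, "rb") as f2:
                assert f1.read() == f2.read()
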