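"""CTC loss, attention loss, hybrid mixing, decoding and training contracts."""

import numpy as np
import pytest

from eatsound.features import FeatureConfig
from eatsound.model import (HybridModel, ModelConfig, PosteriorTrack, Vocab,
                            ctc_feasible, ctc_loss, hybrid_loss,
                            teacher_forced_nll, train)

from oracles import brute_force_best_sequence, brute_force_ctc_nll


def _random_posteriors(rng, T, K=5):
    return rng.dirichlet(np.ones(K), size=T)


class TestCtcLoss:
    def test_single_frame_certain(self):
        p = np.zeros((1, 5))
        p[0, 1] = 1.0
        with np.errstate(divide="ignore"):
            assert ctc_loss(np.log(p), ["L"]) == pytest.approx(0.0, abs=1e-12)

    def test_two_frame_worked_example(self):
        # uniform 0.5/0.5 over {blank, L}: p([L]) = P(LL)+P(L,b)+P(b,L) = 0.75
        p = np.zeros((2, 5))
        p[:, 0] = 0.5
        p[:, 1] = 0.5
        with np.errstate(divide="ignore"):
            loss = ctc_loss(np.log(p), ["L"])
        assert loss == pytest.approx(-np.log(0.75), abs=1e-12)

    def test_repeat_needs_intervening_blank(self):
        p = np.full((2, 5), 0.2)
        with pytest.raises(ValueError, match="infeasible"):
            ctc_loss(np.log(p), ["L", "L"])
        assert not ctc_feasible(2, ["L", "L"])
        assert ctc_feasible(3, ["L", "L"])

    def test_matches_brute_force_enumeration(self, rng):
        for _ in range(40):
            T = int(rng.integers(1, 7))
            L = int(rng.integers(0, 4))
            target = list(rng.integers(1, 5, size=L))
            reps = sum(1 for a, b in zip(target, target[1:]) if a == b)
            if T < L + reps:
                continue
            p = _random_posteriors(rng, T)
            got = ctc_loss(np.log(p), target)
            assert got == pytest.approx(brute_force_ctc_nll(p, target),
                                        abs=1e-8)

    def test_distribution_normalizes(self, rng):
        # summed over every collapsed sequence, CTC is a distribution
        from itertools import product as iproduct
        T = 3
        p = _random_posteriors(rng, T)
        total = 0.0
        for L in range(T + 1):
            for seq in iproduct(range(1, 5), repeat=L):
                if not ctc_feasible(T, list(seq)):
                    continue
                total += np.exp(-ctc_loss(np.log(p), list(seq)))
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_gradient_matches_finite_differences(self, rng):
        from eatsound.autodiff import parameter
        from eatsound.model import ctc_nll
        logits = parameter(rng.normal(size=(4, 5)))
        lp = logits.log_softmax(axis=-1)
        ctc_nll(lp, [1, 2]).backward()
        eps = 1e-6
        for idx in [(0, 0), (1, 1), (2, 2), (3, 4)]:
            base = logits.data.copy()
            logits_p = base.copy()
            logits_p[idx] += eps
            logits_m = base.copy()
            logits_m[idx] -= eps

            def nll(z):
                z = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
                from eatsound.autodiff import constant
                return ctc_nll(constant(z), [1, 2]).item()

            num = (nll(logits_p) - nll(logits_m)) / (2 * eps)
            assert logits.grad[idx] == pytest.approx(num, abs=1e-5)


class TestAttentionAndHybrid:
    def test_perfect_prediction_zero_loss(self):
        lp = np.full((3, 6), -50.0)
        ids = [Vocab.DEC_ID["L"], Vocab.DEC_ID["R"], Vocab.EOS]
        for t, k in enumerate(ids):
            lp[t, k] = 0.0
        assert teacher_forced_nll(lp, ["L", "R"]) == pytest.approx(0.0)

    def test_uniform_prediction_ln6_per_token(self):
        lp = np.full((4, 6), -np.log(6.0))
        assert teacher_forced_nll(lp, ["L", "R", "S"]) == pytest.approx(np.log(6))

    def test_empty_target_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            teacher_forced_nll(np.zeros((1, 6)), [])

    def test_attention_weights_normalized(self, rng):
        model = HybridModel(10, ModelConfig(enc_hidden=8, dec_hidden=8,
                                            att_dim=8, seed=0))
        enc = rng.normal(size=(12, 16))
        att = model.attention_weights(enc, ["L", "R"])
        assert att.shape == (3, 12)              # 2 tokens + eos
        assert np.allclose(att.sum(axis=1), 1.0, atol=1e-9)

    def test_hybrid_loss_limits_and_linearity(self):
        assert hybrid_loss(2.0, 1.0, 1.0) == 2.0
        assert hybrid_loss(2.0, 1.0, 0.0) == 1.0
        assert hybrid_loss(2.0, 1.0, 0.7) == pytest.approx(1.7)
        for a in (0.0, 0.25, 0.5, 0.75, 1.0):
            assert hybrid_loss(3.0, 5.0, a) == pytest.approx(3.0 * a + 5.0 * (1 - a))

    def test_alpha_out_of_range(self):
        with pytest.raises(ValueError):
            hybrid_loss(1.0, 1.0, 1.5)
        with pytest.raises(ValueError):
            ModelConfig(alpha=-0.1)


class TestPosteriorsAndDecoding:
    @pytest.fixture()
    def small_model(self):
        return HybridModel(46, ModelConfig(enc_hidden=12, dec_hidden=12,
                                           att_dim=12, seed=3))

    def test_posterior_rows_sum_to_one(self, small_model, rng):
        feats = rng.normal(size=(20, 46))
        post = small_model.frame_posteriors(feats)
        assert post.probs.shape == (20, 5)
        assert np.allclose(post.probs.sum(axis=1), 1.0, atol=1e-9)

    def test_posteriors_deterministic(self, small_model, rng):
        feats = rng.normal(size=(15, 46))
        a = small_model.frame_posteriors(feats).probs
        b = small_model.frame_posteriors(feats).probs
        assert np.array_equal(a, b)

    def test_feature_width_mismatch(self, small_model, rng):
        with pytest.raises(ValueError, match="feature width"):
            small_model.frame_posteriors(rng.normal(size=(10, 40)))

    def test_posterior_track_validation(self):
        with pytest.raises(ValueError):
            PosteriorTrack(probs=np.full((3, 5), 0.5))

    def test_ctc_only_decode_matches_exhaustive_search(self, small_model, rng):
        # with alpha=1 and a wide beam, joint decoding must return the best
        # sequence under exhaustive CTC scoring on tiny inputs
        for trial in range(8):
            feats = rng.normal(size=(4, 46)) * 3.0
            probs = small_model.frame_posteriors(feats).probs
            expected = brute_force_best_sequence(probs)
            got = small_model.decode_joint(feats, beam=64, alpha=1.0)
            got_ids = tuple(Vocab.CTC_ID[t] for t in got)
            assert got_ids == expected

    def test_wider_beam_never_scores_worse(self, small_model, rng):
        feats = rng.normal(size=(5, 46)) * 2.0
        probs = small_model.frame_posteriors(feats).probs
        with np.errstate(divide="ignore"):
            lp = np.log(probs)

        def seq_score(tokens):
            if not tokens:
                return float(lp[:, 0].sum())     # empty sequence: all blank
            return -ctc_loss(lp, tokens)

        scores = [seq_score(small_model.decode_joint(feats, beam=b, alpha=1.0))
                  for b in (1, 2, 4, 16)]
        assert all(b >= a - 1e-9 for a, b in zip(scores, scores[1:]))

    def test_all_blank_posterior_decodes_empty(self, rng):
        # force the CTC head to emit blank with certainty
        model = HybridModel(46, ModelConfig(enc_hidden=8, dec_hidden=8,
                                            att_dim=8, seed=1))
        model.params["ctc_W"].data[:] = 0.0
        model.params["ctc_b"].data[:] = np.array([50.0, 0, 0, 0, 0])
        feats = rng.normal(size=(10, 46))
        assert model.decode_joint(feats, beam=4, alpha=1.0) == []


class TestTraining:
    def test_loss_history_decreases(self, fixture_model):
        model, history = fixture_model
        assert len(history) >= 2
        assert all(np.isfinite(h["hybrid_loss"]) for h in history)
        assert history[-1]["hybrid_loss"] < history[0]["hybrid_loss"]

    def test_degenerate_alpha_runs_complete(self, tiny_dataset):
        sub = type(tiny_dataset)(rows=tiny_dataset.rows[:4])
        for alpha in (0.0, 1.0):
            cfg = ModelConfig(enc_hidden=8, dec_hidden=8, att_dim=8,
                              epochs=1, alpha=alpha, seed=0)
            model, history = train(sub, None, cfg)
            assert len(history) == 1
            assert np.isfinite(history[0]["hybrid_loss"])

    def test_training_reproducible(self, tiny_dataset):
        sub = type(tiny_dataset)(rows=tiny_dataset.rows[:3])
        cfg = ModelConfig(enc_hidden=8, dec_hidden=8, att_dim=8, epochs=1,
                          seed=5)
        m1, h1 = train(sub, None, cfg)
        m2, h2 = train(sub, None, cfg)
        assert h1 == h2
        assert all(np.array_equal(m1.params[k].data, m2.params[k].data)
                   for k in m1.params)

    def test_empty_manifest_rejected(self):
        from eatsound.io import DatasetManifest
        with pytest.raises(ValueError, match="empty"):
            train(DatasetManifest(rows=[]))


class TestCheckpoint:
    def test_save_load_round_trip(self, tmp_path, rng):
        model = HybridModel(46, ModelConfig(enc_hidden=8, dec_hidden=8,
                                            att_dim=8, seed=2))
        p = str(tmp_path / "m.npz")
        model.save(p)
        loaded = HybridModel.load(p)
        feats = rng.normal(size=(12, 46))
        assert np.array_equal(model.frame_posteriors(feats).probs,
                              loaded.frame_posteriors(feats).probs)
        assert loaded.config == model.config
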