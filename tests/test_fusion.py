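import math

import numpy as np
import pytest

from stsfuse.corpus_io import Corpus, SentencePair
from stsfuse.encoders import EncoderConfig
from stsfuse.fusion import (
    FusionParameters,
    STSModel,
    TrainConfig,
    concat_representations,
    fuse,
    init_fusion_parameters,
    predict_score,
    train,
)
from stsfuse.onehot import ngram_overlap
from stsfuse.synthgen import CLINICAL_VOCAB, GeneratorConfig, generate

TINY_ENC = EncoderConfig(
    embedding_dim=8,
    hidden_dim=6,
    cnn_filters=6,
    transformer_depth=1,
    transformer_heads=2,
    transformer_dim=8,
    transformer_ffn=16,
    max_len=48,
)


def scalar_loop_fuse(D, O, p):
    """Independent scalar re-implementation of the four gate equations."""
    d = p.b_d.size
    d_norm = [math.tanh(sum(p.W_d[i][j] * D[j] for j in range(len(D))) + p.b_d[i])
              for i in range(d)]
    o_norm = [math.tanh(sum(p.W_o[i][j] * O[j] for j in range(len(O))) + p.b_o[i])
              for i in range(d)]
    cat = d_norm + o_norm
    gate = [
        1.0 / (1.0 + math.exp(-(sum(p.W_f[i][j] * cat[j] for j in range(2 * d))
                                + p.b_f[i])))
        for i in range(d)
    ]
    r = [gate[i] * d_norm[i] + (1 - gate[i]) * o_norm[i] for i in range(d)]
    return d_norm, o_norm, gate, r


class TestFuse:
    def _params(self, d=3, d_D=4, n_feat=5, seed=0):
        return init_fusion_parameters(d, d_D, n_feat, seed=seed)

    def test_gate_saturation(self):
        p = self._params()
        p.W_f = np.zeros_like(p.W_f)
        p.b_f = np.full_like(p.b_f, 50.0)
        out = fuse(np.ones(4), np.ones(5), p)
        np.testing.assert_allclose(out.gate, 1.0, atol=1e-20)
        np.testing.assert_allclose(out.r, out.d_norm, atol=1e-12)

    def test_symmetric_gate(self):
        p = self._params()
        p.W_f = np.zeros_like(p.W_f)
        p.b_f = np.zeros_like(p.b_f)
        out = fuse(np.ones(4), np.ones(5), p)
        np.testing.assert_array_equal(out.gate, np.full(3, 0.5))
        np.testing.assert_allclose(out.r, (out.d_norm + out.o_norm) / 2.0)

    def test_hand_evaluated_small_case(self):
        p = FusionParameters(
            W_d=np.array([[1.0, -1.0], [0.5, 0.0]]),
            b_d=np.array([0.1, -0.2]),
            W_o=np.array([[2.0], [1.0]]),
            b_o=np.array([0.0, 0.3]),
            W_f=np.array([[0.2, -0.1, 0.4, 0.0], [0.0, 0.3, -0.2, 0.1]]),
            b_f=np.array([0.05, -0.05]),
            head_w=np.array([1.0, 1.0]),
            head_b=0.0,
        )
        D, O = np.array([0.5, -1.0]), np.array([0.25])
        out = fuse(D, O, p)
        d_norm, o_norm, gate, r = scalar_loop_fuse(D, O, p)
        np.testing.assert_allclose(out.d_norm, d_norm, atol=1e-10)
        np.testing.assert_allclose(out.o_norm, o_norm, atol=1e-10)
        np.testing.assert_allclose(out.gate, gate, atol=1e-10)
        np.testing.assert_allclose(out.r, r, atol=1e-10)

    def test_scalar_loop_oracle_50_draws(self, rng):
        for k in range(50):
            d, d_D, n_feat = int(rng.integers(1, 5)), int(rng.integers(1, 6)), 17
            p = init_fusion_parameters(d, d_D, n_feat, seed=k)
            D = rng.normal(size=d_D)
            O = rng.normal(size=n_feat)
            out = fuse(D, O, p)
            _, _, gate, r = scalar_loop_fuse(D, O, p)
            np.testing.assert_allclose(out.gate, gate, atol=1e-8)
            np.testing.assert_allclose(out.r, r, atol=1e-8)
            assert np.all((out.gate > 0) & (out.gate < 1))
            lo = np.minimum(out.d_norm, out.o_norm)
            hi = np.maximum(out.d_norm, out.o_norm)
            assert np.all(out.r >= lo - 1e-12) and np.all(out.r <= hi + 1e-12)

    def test_non_finite_parameters_rejected(self):
        p = self._params()
        with pytest.raises((ValueError, FloatingPointError)):
            p.W_d[0, 0] = np.nan
            FusionParameters(**{k: getattr(p, k) for k in (
                "W_d", "b_d", "W_o", "b_o", "W_f", "b_f", "head_w", "head_b")})

    def test_shape_validation(self):
        with pytest.raises(ValueError):
            FusionParameters(
                W_d=np.zeros((2, 3)), b_d=np.zeros(2),
                W_o=np.zeros((2, 5)), b_o=np.zeros(2),
                W_f=np.zeros((2, 3)),  # must be (2, 4)
                b_f=np.zeros(2), head_w=np.zeros(2), head_b=0.0,
            )


class TestConcat:
    def test_shape_range_and_shared_projection(self):
        p = init_fusion_parameters(3, 4, 5, seed=1)
        D, O = np.ones(4), np.ones(5)
        cat = concat_representations(D, O, p)
        assert cat.shape == (6,)
        assert np.all(np.abs(cat) < 1.0)
        np.testing.assert_array_equal(cat[:3], fuse(D, O, p).d_norm)


class TestPredictScore:
    def test_zero_head_gives_midpoint(self):
        p = init_fusion_parameters(3, 4, 5)
        p.head_w = np.zeros(3)
        p.head_b = 0.0
        assert predict_score(np.ones(3), p) == pytest.approx(2.5)

    def test_saturated_head(self):
        p = init_fusion_parameters(3, 4, 5)
        p.head_w = np.zeros(3)
        p.head_b = 100.0
        assert predict_score(np.ones(3), p) == pytest.approx(5.0, abs=1e-9)

    def test_hand_evaluated(self):
        p = init_fusion_parameters(2, 2, 2)
        p.head_w = np.array([0.3, -0.2])
        p.head_b = 0.1
        r = np.array([0.5, 0.25])
        expected = 5.0 / (1.0 + math.exp(-(0.3 * 0.5 - 0.2 * 0.25 + 0.1)))
        assert predict_score(r, p) == pytest.approx(expected, abs=1e-10)

    def test_always_inside_valid_range(self, rng):
        p = init_fusion_parameters(4, 4, 4, seed=2)
        for _ in range(20):
            s = predict_score(rng.normal(size=4), p)
            assert 0.0 < s < 5.0


def _ngo_corpus(n, seed):
    """Corpus whose gold is exactly 5 * unigram overlap (zero noise)."""
    return generate(GeneratorConfig(n_pairs=n, noise_sd=0.0, seed=seed))


class TestTrain:
    def test_onehot_learns_ngo_target(self):
        corpus = _ngo_corpus(300, seed=5)
        train_c = Corpus(corpus.pairs[:240], "train")
        dev_c = Corpus(corpus.pairs[240:], "dev")
        cfg = TrainConfig(mode="onehot_only", max_epochs=200, patience=20, seed=0)
        result = train(train_c, dev_c, cfg)
        assert result.best_dev_pearson >= 0.95

    def test_determinism(self, tiny_corpus):
        train_c = Corpus(tiny_corpus.pairs[:30], "train")
        dev_c = Corpus(tiny_corpus.pairs[30:], "dev")
        cfg = TrainConfig(mode="gated", encoder="cnn", max_epochs=3, seed=7,
                          encoder_config=TINY_ENC)
        a = train(train_c, dev_c, cfg)
        b = train(train_c, dev_c, cfg)
        assert a.best_dev_pearson == b.best_dev_pearson
        for k in a.model.state_dict():
            np.testing.assert_array_equal(
                a.model.state_dict()[k], b.model.state_dict()[k]
            )

    def test_single_pair_overfits(self):
        pair = SentencePair("only", "nurse visit chest pain", "nurse visit", gold=3.0)
        corpus = Corpus([pair], "single")
        cfg = TrainConfig(mode="onehot_only", max_epochs=300, seed=0, lr=5e-3)
        result = train(corpus, None, cfg)
        losses = [h["train_mse"] for h in result.history]
        assert losses[-1] < 1e-2
        assert losses[-1] < losses[0]

    def test_empty_dev_falls_back_to_fixed_epochs(self, tiny_corpus):
        cfg = TrainConfig(mode="onehot_only", max_epochs=5, seed=0)
        result = train(tiny_corpus, None, cfg)
        assert len(result.history) == 5
        assert result.best_dev_pearson is None

    @pytest.mark.parametrize("encoder", ["cnn", "lstm", "transformer"])
    @pytest.mark.parametrize("mode", ["encoder_only", "concat", "gated"])
    def test_grid_of_valid_runs(self, mode, encoder, tiny_corpus):
        # together with onehot_only this enumerates the 10 valid combinations
        train_c = Corpus(tiny_corpus.pairs[:32], "train")
        dev_c = Corpus(tiny_corpus.pairs[32:], "dev")
        cfg = TrainConfig(mode=mode, encoder=encoder, max_epochs=1, seed=0,
                          batch_size=8, encoder_config=TINY_ENC)
        result = train(train_c, dev_c, cfg)
        preds = result.model.predict(dev_c)
        assert np.all((preds > 0) & (preds < 5))

    def test_invalid_mode_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(mode="bogus")
        with pytest.raises(ValueError):
            TrainConfig(encoder="gru")


class TestCheckpoint:
    def test_round_trip_predictions(self, tiny_corpus, tmp_path):
        train_c = Corpus(tiny_corpus.pairs[:30], "train")
        dev_c = Corpus(tiny_corpus.pairs[30:], "dev")
        cfg = TrainConfig(mode="gated", encoder="cnn", max_epochs=2, seed=1,
                          encoder_config=TINY_ENC)
        result = train(train_c, dev_c, cfg)
        path = tmp_path / "model.npz"
        result.model.save_checkpoint(path)
        loaded = STSModel.load_checkpoint(path)
        np.testing.assert_allclose(
            loaded.predict(dev_c), result.model.predict(dev_c), atol=1e-12
        )
        assert loaded.config.mode == "gated"

    def test_onehot_checkpoint_without_vocab(self, tiny_corpus, tmp_path):
        cfg = TrainConfig(mode="onehot_only", max_epochs=2, seed=1)
        result = train(
            Corpus(tiny_corpus.pairs[:30], "t"),
            Corpus(tiny_corpus.pairs[30:], "d"),
            cfg,
        )
        path = tmp_path / "model.npz"
        result.model.save_checkpoint(path)
        loaded = STSModel.load_checkpoint(path)
        np.testing.assert_allclose(
            loaded.predict(tiny_corpus), result.model.predict(tiny_corpus)
        )
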