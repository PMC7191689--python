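import numpy as np
import pytest

from stsfuse.encoders import (
    CnnEncoder,
    EncoderConfig,
    LstmEncoder,
    TransformerEncoder,
    Vocab,
    build_encoder,
)
from stsfuse.preprocess import TokenizedPair

SMALL = EncoderConfig(
    embedding_dim=6,
    hidden_dim=5,
    cnn_filters=4,
    transformer_depth=1,
    transformer_heads=2,
    transformer_dim=8,
    transformer_ffn=12,
    max_len=16,
)


@pytest.fixture
def vocab():
    return Vocab(["nurse", "visit", "chest", "pain", "fever", "cough", "wound"])


@pytest.fixture
def pair():
    return TokenizedPair("p", ["nurse", "visit", "chest"], ["fever", "cough"])


def swapped(p):
    return TokenizedPair(p.pair_id + "-swap", p.tokens2, p.tokens1)


class TestVocab:
    def test_specials_reserved(self, vocab):
        assert vocab.itos[:4] == ["[PAD]", "[UNK]", "[CLS]", "[SEP]"]

    def test_unknown_maps_to_unk(self, vocab):
        assert vocab.encode(["zzz"]) == [1]

    def test_from_pairs_dedupes(self):
        pairs = [TokenizedPair("a", ["x", "x"], ["y"])]
        v = Vocab.from_pairs(pairs)
        assert len(v) == 6


class TestCnnEncoder:
    def test_output_dim(self, vocab):
        enc = CnnEncoder(vocab, SMALL, seed=0)
        assert enc.output_dim == 2 * 4 * 3
        out = enc.encode_batch([TokenizedPair("p", ["nurse"], ["visit"])])
        assert out.shape == (1, enc.output_dim)

    def test_identical_sentences_give_equal_halves(self, vocab):
        enc = CnnEncoder(vocab, SMALL, seed=0)
        p = TokenizedPair("p", ["nurse", "visit"], ["nurse", "visit"])
        out = enc.encode_batch([p]).data[0]
        half = enc.output_dim // 2
        np.testing.assert_array_equal(out[:half], out[half:])

    def test_swap_symmetry(self, vocab, pair):
        enc = CnnEncoder(vocab, SMALL, seed=0)
        a = enc.encode_batch([pair]).data[0]
        b = enc.encode_batch([swapped(pair)]).data[0]
        half = enc.output_dim // 2
        np.testing.assert_array_equal(a[:half], b[half:])
        np.testing.assert_array_equal(a[half:], b[:half])

    def test_width1_identity_filter_recovers_embedding_mean(self, vocab):
        cfg = EncoderConfig(
            embedding_dim=4, cnn_filters=4, cnn_filter_widths=(1,), max_len=16
        )
        enc = CnnEncoder(vocab, cfg, seed=0)
        # identity filter, zero bias, positive embeddings so ReLU is inactive
        enc.params["conv_w1"].data = np.eye(4)
        enc.params["conv_b1"].data = np.zeros(4)
        enc.params["embedding"].data = np.abs(enc.params["embedding"].data) + 0.1
        p = TokenizedPair("p", ["nurse", "visit"], ["chest"])
        out = enc.encode_batch([p]).data[0]
        ids = vocab.encode(["nurse", "visit"])
        expected = enc.params["embedding"].data[ids].mean(axis=0)
        np.testing.assert_allclose(out[:4], expected, atol=1e-12)

    def test_sentence_shorter_than_widest_filter(self, vocab):
        enc = CnnEncoder(vocab, SMALL, seed=0)
        p = TokenizedPair("p", ["nurse"], ["visit"])
        out = enc.encode_batch([p])
        assert np.all(np.isfinite(out.data))

    def test_siamese_weight_identity(self, vocab):
        enc = CnnEncoder(vocab, SMALL, seed=0)
        # one shared parameter set: both towers read the very same tensors
        assert len(enc.parameters()) == 1 + 2 * len(SMALL.cnn_filter_widths)


class TestLstmEncoder:
    def test_output_dim(self, vocab, pair):
        enc = LstmEncoder(vocab, SMALL, seed=0)
        assert enc.output_dim == 4 * SMALL.hidden_dim
        assert enc.encode_batch([pair]).shape == (1, 4 * SMALL.hidden_dim)

    def test_swap_symmetry(self, vocab, pair):
        enc = LstmEncoder(vocab, SMALL, seed=0)
        a = enc.encode_batch([pair]).data[0]
        b = enc.encode_batch([swapped(pair)]).data[0]
        half = enc.output_dim // 2
        np.testing.assert_array_equal(a[:half], b[half:])
        np.testing.assert_array_equal(a[half:], b[:half])

    def test_one_token_sentence_fwd_bwd_same_input(self, vocab):
        enc = LstmEncoder(vocab, SMALL, seed=0)
        # tie backward weights to forward weights: on a 1-token sentence both
        # directions then compute the identical state from the same input
        for name in ("wx", "wh", "b"):
            enc.params[f"{name}_bwd"].data = enc.params[f"{name}_fwd"].data.copy()
        p = TokenizedPair("p", ["nurse"], ["visit"])
        out = enc.encode_batch([p]).data[0]
        h = SMALL.hidden_dim
        np.testing.assert_allclose(out[:h], out[h : 2 * h])

    def test_zero_weights_give_zero_states(self, vocab, pair):
        enc = LstmEncoder(vocab, SMALL, seed=0)
        for d in ("fwd", "bwd"):
            enc.params[f"wx_{d}"].data[:] = 0.0
            enc.params[f"wh_{d}"].data[:] = 0.0
            enc.params[f"b_{d}"].data[:] = 0.0
        out = enc.encode_batch([pair]).data
        np.testing.assert_allclose(out, np.zeros_like(out))

    def test_variable_lengths_batch(self, vocab):
        enc = LstmEncoder(vocab, SMALL, seed=0)
        long_pair = TokenizedPair("a", ["nurse"] * 6, ["visit"] * 4)
        short_pair = TokenizedPair("b", ["nurse"], ["visit"])
        batch = enc.encode_batch([long_pair, short_pair]).data
        solo = enc.encode_batch([short_pair]).data[0]
        np.testing.assert_allclose(batch[1], solo, atol=1e-12)


class TestTransformerEncoder:
    def test_output_dim_and_determinism(self, vocab, pair):
        enc1 = TransformerEncoder(vocab, SMALL, seed=0)
        enc2 = TransformerEncoder(vocab, SMALL, seed=0)
        a = enc1.encode_batch([pair]).data
        b = enc2.encode_batch([pair]).data
        assert a.shape == (1, SMALL.transformer_dim)
        np.testing.assert_array_equal(a, b)

    def test_depth_zero_returns_cls_embedding(self, vocab, pair):
        cfg = EncoderConfig(
            transformer_depth=0, transformer_heads=2, transformer_dim=8, max_len=16
        )
        enc = TransformerEncoder(vocab, cfg, seed=0)
        out = enc.encode_batch([pair]).data[0]
        cls_id = vocab.stoi["[CLS]"]
        expected = (
            enc.params["embedding"].data[cls_id]
            + enc.params["pos"].data[0]
            + enc.params["segment"].data[0]
        )
        np.testing.assert_allclose(out, expected, atol=1e-12)

    def test_uniform_attention_hand_trace(self, vocab):
        """With Wq=Wk=0, Wv=Wo=I and a disabled FFN, one block reduces to a
        hand-computable uniform mixture of value vectors + layer norms."""
        cfg = EncoderConfig(
            transformer_depth=1, transformer_heads=1, transformer_dim=8, max_len=16
        )
        enc = TransformerEncoder(vocab, cfg, seed=0)
        d = cfg.transformer_dim
        enc.params["l0_wq"].data = np.zeros((d, d))
        enc.params["l0_wk"].data = np.zeros((d, d))
        enc.params["l0_wv"].data = np.eye(d)
        enc.params["l0_wo"].data = np.eye(d)
        enc.params["l0_ffn1"].data[:] = 0.0
        enc.params["l0_ffn1b"].data[:] = 0.0
        enc.params["l0_ffn2"].data[:] = 0.0
        enc.params["l0_ffn2b"].data[:] = 0.0
        pair = TokenizedPair("p", ["nurse"], ["visit"])
        out = enc.encode_batch([pair]).data[0]

        # independent numpy re-computation
        ids = [vocab.stoi[t] for t in ("[CLS]", "nurse", "[SEP]", "visit", "[SEP]")]
        segs = [0, 0, 0, 1, 1]
        e = np.stack(
            [
                enc.params["embedding"].data[i]
                + enc.params["pos"].data[k]
                + enc.params["segment"].data[s]
                for k, (i, s) in enumerate(zip(ids, segs))
            ]
        )

        def layer_norm(x, g, b):
            mu = x.mean(-1, keepdims=True)
            var = ((x - mu) ** 2).mean(-1, keepdims=True)
            return (x - mu) / np.sqrt(var + 1e-6) * g + b

        mixed = e + e.mean(axis=0)  # uniform attention mixes all positions
        x = layer_norm(
            mixed, enc.params["l0_ln1_g"].data, enc.params["l0_ln1_b"].data
        )
        x = layer_norm(x, enc.params["l0_ln2_g"].data, enc.params["l0_ln2_b"].data)
        np.testing.assert_allclose(out, x[0], atol=1e-10)

    def test_truncation_beyond_max_len(self, vocab):
        cfg = EncoderConfig(
            transformer_depth=1, transformer_heads=2, transformer_dim=8, max_len=8
        )
        enc = TransformerEncoder(vocab, cfg, seed=0)
        p = TokenizedPair("p", ["nurse"] * 10, ["visit"] * 10)
        ids, segs = enc._serialize(p)
        assert len(ids) == 8 and len(segs) == 8
        out = enc.encode_batch([p])
        assert np.all(np.isfinite(out.data))

    def test_pretrained_bundle_round_trip(self, vocab, pair, tmp_path):
        enc = TransformerEncoder(vocab, SMALL, seed=0)
        before = enc.encode_batch([pair]).data
        enc.save_weights(tmp_path / "bundle")
        fresh = TransformerEncoder(vocab, SMALL, seed=99)
        assert not np.allclose(fresh.encode_batch([pair]).data, before)
        fresh.load_weights(tmp_path / "bundle")
        np.testing.assert_array_equal(fresh.encode_batch([pair]).data, before)

    def test_vocab_mismatch_rejected(self, vocab, tmp_path):
        enc = TransformerEncoder(vocab, SMALL, seed=0)
        enc.save_weights(tmp_path / "bundle")
        other = TransformerEncoder(Vocab(["different"]), SMALL, seed=0)
        with pytest.raises(ValueError, match="vocabulary"):
            other.load_weights(tmp_path / "bundle")


class TestGradientFlow:
    @pytest.mark.parametrize("name", ["cnn", "lstm", "transformer"])
    def test_every_parameter_receives_gradient(self, name, vocab):
        enc = build_encoder(name, vocab, SMALL, seed=1)
        batch = [
            TokenizedPair("a", ["nurse", "visit"], ["chest", "pain"]),
            TokenizedPair("b", ["fever"], ["cough", "wound", "nurse"]),
        ]
        out = enc.encode_batch(batch)
        (out * out).sum().backward()
        for pname, p in enc.params.items():
            assert p.grad is not None, pname
            assert np.all(np.isfinite(p.grad)), pname
            assert np.linalg.norm(p.grad) > 0, pname


class TestBuildEncoder:
    def test_unknown_name(self, vocab):
        with pytest.raises(ValueError):
            build_encoder("gru", vocab, SMALL)

    def test_encode_pair_returns_tagged_representation(self, vocab, pair):
        enc = build_encoder("cnn", vocab, SMALL, seed=0)
        rep = enc.encode_pair(pair)
        assert rep.encoder_tag == "cnn"
        assert rep.values.shape == (enc.output_dim,)
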