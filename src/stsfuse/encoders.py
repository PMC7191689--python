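"""Neural pair encoders producing the distributed representation of a pair.

Three interchangeable encoders are provided:

* :class:`CnnEncoder` — Siamese convolutional towers (shared weights); each
  sentence is convolved over token embeddings, passed through a ReLU and
  average-pooled over positions; the pair vector is the concatenation of the
  two tower outputs.
* :class:`LstmEncoder` — Siamese bidirectional LSTM towers; the pair vector
  concatenates, per sentence, the final forward state and the backward state
  at the first position.
* :class:`TransformerEncoder` — a single self-attention stack over
  ``[CLS] s1 [SEP] s2 [SEP]`` with segment ids; the pair vector is the final
  hidden state at the ``[CLS]`` position.  Weights are randomly initialized
  and trained end-to-end by default; externally pre-trained weights can be
  loaded via :meth:`TransformerEncoder.load_weights`.

All encoders operate on token lists from :mod:`stsfuse.preprocess` and expose
``encode_batch`` (differentiable, for training) plus ``encode_pair`` (numpy
convenience returning a :class:`PairRepresentation`).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .autograd import Tensor, concat, parameter, softmax
from .corpus_io import EmbeddingTable
from .preprocess import TokenizedPair

logger = logging.getLogger(__name__)

__all__ = [
    "CnnEncoder",
    "EncoderConfig",
    "LstmEncoder",
    "PairRepresentation",
    "TransformerEncoder",
    "Vocab",
    "build_encoder",
]

PAD, UNK, CLS, SEP = "[PAD]", "[UNK]", "[CLS]", "[SEP]"


@dataclass
class PairRepresentation:
    """Dense vector describing a sentence pair, tagged by its encoder."""

    values: np.ndarray
    encoder_tag: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite entries in pair representation")


@dataclass
class EncoderConfig:
    """Hyperparameters shared by the three encoders."""

    embedding_dim: int = 32
    hidden_dim: int = 32
    cnn_filter_widths: Tuple[int, ...] = (1, 2, 3)
    cnn_filters: int = 32
    transformer_depth: int = 2
    transformer_heads: int = 2
    transformer_dim: int = 64
    transformer_ffn: int = 128
    max_len: int = 64

    def __post_init__(self) -> None:
        dims = (
            self.embedding_dim,
            self.hidden_dim,
            self.cnn_filters,
            self.transformer_heads,
            self.transformer_dim,
            self.transformer_ffn,
            self.max_len,
        )
        if any(d <= 0 for d in dims) or any(w <= 0 for w in self.cnn_filter_widths):
            raise ValueError("all encoder dimensions must be positive")
        if self.transformer_depth < 0:
            raise ValueError("transformer depth must be >= 0")
        if self.transformer_dim % self.transformer_heads:
            raise ValueError("transformer_dim must be divisible by heads")


class Vocab:
    """Token -> integer id mapping with reserved special symbols."""

    def __init__(self, tokens: Iterable[str]) -> None:
        self.itos: List[str] = [PAD, UNK, CLS, SEP]
        seen = set(self.itos)
        for tok in tokens:
            if tok not in seen:
                seen.add(tok)
                self.itos.append(tok)
        self.stoi: Dict[str, int] = {t: i for i, t in enumerate(self.itos)}

    @classmethod
    def from_pairs(cls, pairs: Sequence[TokenizedPair]) -> "Vocab":
        def stream():
            for p in pairs:
                yield from p.tokens1
                yield from p.tokens2

        return cls(stream())

    def __len__(self) -> int:
        return len(self.itos)

    def encode(self, tokens: Sequence[str]) -> List[int]:
        unk = self.stoi[UNK]
        return [self.stoi.get(t, unk) for t in tokens]


def _pad_batch(
    seqs: Sequence[Sequence[int]], min_len: int = 1
) -> Tuple[np.ndarray, np.ndarray]:
    """Right-pad id sequences with 0; returns (ids, mask) as [B, L] arrays."""
    max_len = max(min_len, max((len(s) for s in seqs), default=1))
    ids = np.zeros((len(seqs), max_len), dtype=int)
    mask = np.zeros((len(seqs), max_len), dtype=float)
    for i, s in enumerate(seqs):
        ids[i, : len(s)] = s
        mask[i, : len(s)] = 1.0
    return ids, mask


class _EncoderBase:
    """Shared parameter bookkeeping for the three encoders."""

    tag: str = "base"

    def __init__(self, vocab: Vocab, config: EncoderConfig) -> None:
        self.vocab = vocab
        self.config = config
        self.params: Dict[str, Tensor] = {}

    def _param(self, name: str, rng: np.random.Generator, *shape: int,
               scale: Optional[float] = None) -> Tensor:
        p = parameter(rng, *shape, scale=scale)
        self.params[name] = p
        return p

    def parameters(self) -> List[Tensor]:
        return list(self.params.values())

    def state_dict(self) -> Dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state(self, state: Dict[str, np.ndarray]) -> None:
        for k, v in state.items():
            if k not in self.params:
                raise KeyError(f"unknown encoder parameter {k!r}")
            if self.params[k].data.shape != v.shape:
                raise ValueError(f"shape mismatch for parameter {k!r}")
            self.params[k].data = np.asarray(v, dtype=float).copy()

    def init_embeddings(self, table: EmbeddingTable) -> None:
        """Overwrite the trainable embedding rows from a pretrained table."""
        emb = self.params["embedding"]
        if table.dimension != emb.data.shape[1]:
            raise ValueError(
                f"embedding table dimension {table.dimension} does not match "
                f"encoder embedding_dim {emb.data.shape[1]}"
            )
        n_hit = 0
        for i, tok in enumerate(self.vocab.itos):
            if tok in table:
                emb.data[i] = table.lookup(tok)
                n_hit += 1
        logger.info("initialized %d/%d embedding rows", n_hit, len(self.vocab))

    def encode_batch(self, pairs: Sequence[TokenizedPair]) -> Tensor:
        raise NotImplementedError

    @property
    def output_dim(self) -> int:
        raise NotImplementedError

    def encode_pair(self, pair: TokenizedPair) -> PairRepresentation:
        values = self.encode_batch([pair]).data[0]
        return PairRepresentation(values=values, encoder_tag=self.tag)


class CnnEncoder(_EncoderBase):
    """Siamese CNN: shared convolution filters, ReLU, average pooling."""

    tag = "cnn"
    _short_warned = False

    def __init__(self, vocab: Vocab, config: EncoderConfig, seed: int = 0) -> None:
        super().__init__(vocab, config)
        rng = np.random.default_rng(seed)
        e, f = config.embedding_dim, config.cnn_filters
        self._param("embedding", rng, len(vocab), e)
        for w in config.cnn_filter_widths:
            self._param(f"conv_w{w}", rng, w * e, f)
            self._param(f"conv_b{w}", rng, f, scale=1e-3)

    @property
    def output_dim(self) -> int:
        return 2 * self.config.cnn_filters * len(self.config.cnn_filter_widths)

    def _tower(self, ids: np.ndarray, mask: np.ndarray) -> Tensor:
        cfg = self.config
        B, L = ids.shape
        emb = self.params["embedding"].take_rows(ids)  # [B, L, e]
        lengths = mask.sum(axis=1)
        pooled: List[Tensor] = []
        for w in cfg.cnn_filter_widths:
            n_win = L - w + 1
            windows = concat(
                [emb[:, j : j + n_win, :] for j in range(w)], axis=2
            )  # [B, n_win, w*e]
            flat = windows.reshape(B * n_win, w * cfg.embedding_dim)
            conv = (flat @ self.params[f"conv_w{w}"] + self.params[f"conv_b{w}"]).relu()
            conv = conv.reshape(B, n_win, cfg.cnn_filters)
            # window j is valid when it fits inside the true sentence; short
            # sentences fall back to the single padded window at position 0
            valid = np.arange(n_win)[None, :] <= (lengths[:, None] - w)
            valid = valid.astype(float)
            valid[valid.sum(axis=1) == 0, 0] = 1.0
            counts = valid.sum(axis=1, keepdims=True)
            pooled.append((conv * valid[:, :, None]).sum(axis=1) / counts)
        return concat(pooled, axis=1)  # [B, f * n_widths]

    def encode_batch(self, pairs: Sequence[TokenizedPair]) -> Tensor:
        min_len = max(self.config.cnn_filter_widths)
        if not CnnEncoder._short_warned and any(
            len(p.tokens1) < min_len or len(p.tokens2) < min_len for p in pairs
        ):
            logger.info("sentence shorter than widest filter; padding to width")
            CnnEncoder._short_warned = True
        ids1, m1 = _pad_batch([self.vocab.encode(p.tokens1) for p in pairs], min_len)
        ids2, m2 = _pad_batch([self.vocab.encode(p.tokens2) for p in pairs], min_len)
        return concat([self._tower(ids1, m1), self._tower(ids2, m2)], axis=1)


class LstmEncoder(_EncoderBase):
    """Siamese bidirectional LSTM with shared towers.

    The pair vector is ``[h_fwd_last(s1), h_bwd_first(s1),
    h_fwd_last(s2), h_bwd_first(s2)]`` — dimension ``4 * hidden_dim``.
    """

    tag = "lstm"

    def __init__(self, vocab: Vocab, config: EncoderConfig, seed: int = 0) -> None:
        super().__init__(vocab, config)
        rng = np.random.default_rng(seed)
        e, h = config.embedding_dim, config.hidden_dim
        self._param("embedding", rng, len(vocab), e)
        for d in ("fwd", "bwd"):
            self._param(f"wx_{d}", rng, e, 4 * h)
            self._param(f"wh_{d}", rng, h, 4 * h)
            self._param(f"b_{d}", rng, 4 * h, scale=1e-3)

    @property
    def output_dim(self) -> int:
        return 4 * self.config.hidden_dim

    def _run(self, ids: np.ndarray, mask: np.ndarray, direction: str) -> Tensor:
        h_dim = self.config.hidden_dim
        B, L = ids.shape
        wx = self.params[f"wx_{direction}"]
        wh = self.params[f"wh_{direction}"]
        b = self.params[f"b_{direction}"]
        emb = self.params["embedding"].take_rows(ids)  # [B, L, e]
        h = Tensor(np.zeros((B, h_dim)))
        c = Tensor(np.zeros((B, h_dim)))
        for t in range(L):
            z = emb[:, t, :] @ wx + h @ wh + b
            i = z[:, 0 * h_dim : 1 * h_dim].sigmoid()
            f = z[:, 1 * h_dim : 2 * h_dim].sigmoid()
            g = z[:, 2 * h_dim : 3 * h_dim].tanh()
            o = z[:, 3 * h_dim : 4 * h_dim].sigmoid()
            c_new = f * c + i * g
            h_new = o * c_new.tanh()
            m = mask[:, t][:, None]
            h = h_new * m + h * (1.0 - m)
            c = c_new * m + c * (1.0 - m)
        return h  # state at the last unmasked position

    def _tower(self, token_lists: Sequence[Sequence[str]]) -> Tensor:
        ids, mask = _pad_batch([self.vocab.encode(t) for t in token_lists])
        h_fwd = self._run(ids, mask, "fwd")
        # reverse each sequence in place so a forward scan realizes the
        # backward pass; its final state sits at the original first token
        rev_ids = np.zeros_like(ids)
        for i in range(ids.shape[0]):
            n = int(mask[i].sum())
            rev_ids[i, :n] = ids[i, :n][::-1]
        h_bwd = self._run(rev_ids, mask, "bwd")
        return concat([h_fwd, h_bwd], axis=1)

    def encode_batch(self, pairs: Sequence[TokenizedPair]) -> Tensor:
        t1 = self._tower([p.tokens1 for p in pairs])
        t2 = self._tower([p.tokens2 for p in pairs])
        return concat([t1, t2], axis=1)


class TransformerEncoder(_EncoderBase):
    """Self-attention pair encoder over ``[CLS] s1 [SEP] s2 [SEP]``."""

    tag = "transformer"

    def __init__(self, vocab: Vocab, config: EncoderConfig, seed: int = 0) -> None:
        super().__init__(vocab, config)
        rng = np.random.default_rng(seed)
        d, ffn = config.transformer_dim, config.transformer_ffn
        self._param("embedding", rng, len(vocab), d)
        self._param("pos", rng, config.max_len, d)
        self._param("segment", rng, 2, d)
        for layer in range(config.transformer_depth):
            for name in ("wq", "wk", "wv", "wo"):
                self._param(f"l{layer}_{name}", rng, d, d)
            self._param(f"l{layer}_ffn1", rng, d, ffn)
            self._param(f"l{layer}_ffn1b", rng, ffn, scale=1e-3)
            self._param(f"l{layer}_ffn2", rng, ffn, d)
            self._param(f"l{layer}_ffn2b", rng, d, scale=1e-3)
            for ln in ("ln1", "ln2"):
                self.params[f"l{layer}_{ln}_g"] = Tensor(
                    np.ones(d), requires_grad=True
                )
                self.params[f"l{layer}_{ln}_b"] = Tensor(
                    np.zeros(d), requires_grad=True
                )

    @property
    def output_dim(self) -> int:
        return self.config.transformer_dim

    def _serialize(self, pair: TokenizedPair) -> Tuple[List[int], List[int]]:
        cfg = self.config
        t1 = list(pair.tokens1)
        t2 = list(pair.tokens2)
        overflow = 3 + len(t1) + len(t2) - cfg.max_len
        if overflow > 0:
            # truncate the second sentence first, then the first
            cut2 = min(overflow, max(len(t2) - 1, 0))
            t2 = t2[: len(t2) - cut2]
            overflow -= cut2
            if overflow > 0:
                t1 = t1[: len(t1) - overflow]
            logger.info("pair %s truncated to max_len=%d", pair.pair_id, cfg.max_len)
        ids = (
            [self.vocab.stoi[CLS]]
            + self.vocab.encode(t1)
            + [self.vocab.stoi[SEP]]
            + self.vocab.encode(t2)
            + [self.vocab.stoi[SEP]]
        )
        segments = [0] * (2 + len(t1)) + [1] * (1 + len(t2))
        return ids, segments

    def _layer_norm(self, x: Tensor, gamma: Tensor, beta: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        return centered * (var + 1e-6) ** -0.5 * gamma + beta

    def encode_batch(self, pairs: Sequence[TokenizedPair]) -> Tensor:
        cfg = self.config
        serialized = [self._serialize(p) for p in pairs]
        ids, mask = _pad_batch([s[0] for s in serialized])
        segs, _ = _pad_batch([s[1] for s in serialized])
        B, L = ids.shape
        d, H = cfg.transformer_dim, cfg.transformer_heads
        dh = d // H
        positions = np.broadcast_to(np.arange(L), (B, L))
        x = (
            self.params["embedding"].take_rows(ids)
            + self.params["pos"].take_rows(positions)
            + self.params["segment"].take_rows(segs)
        )
        attn_mask = mask[:, None, None, :].astype(bool)  # [B, 1, 1, L]
        for layer in range(cfg.transformer_depth):
            p = lambda n: self.params[f"l{layer}_{n}"]

            def heads(t: Tensor) -> Tensor:
                return t.reshape(B, L, H, dh).transpose(0, 2, 1, 3)

            q, k, v = heads(x @ p("wq")), heads(x @ p("wk")), heads(x @ p("wv"))
            scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(dh))
            attn = softmax(scores, mask=attn_mask, axis=-1)
            ctx = (attn @ v).transpose(0, 2, 1, 3).reshape(B, L, d)
            x = self._layer_norm(
                x + ctx @ p("wo"), p("ln1_g"), p("ln1_b")
            )
            ffn = (x @ p("ffn1") + p("ffn1b")).relu() @ p("ffn2") + p("ffn2b")
            x = self._layer_norm(x + ffn, p("ln2_g"), p("ln2_b"))
        return x[:, 0, :]  # hidden state at [CLS]

    # -- pretrained bundle ------------------------------------------------
    def load_weights(self, directory: str | Path) -> None:
        """Load a pretrained bundle: ``weights.npz`` + ``vocab.txt``.

        The vocabulary file lists one token per line and must match this
        encoder's vocabulary order; the npz archive maps parameter names to
        arrays with the shapes created by this class.
        """
        directory = Path(directory)
        vocab_tokens = (
            (directory / "vocab.txt").read_text(encoding="utf-8").splitlines()
        )
        if vocab_tokens != self.vocab.itos:
            raise ValueError("pretrained vocabulary does not match corpus vocabulary")
        with np.load(directory / "weights.npz") as bundle:
            self.load_state({k: bundle[k] for k in bundle.files})

    def save_weights(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        (directory / "vocab.txt").write_text(
            "\n".join(self.vocab.itos) + "\n", encoding="utf-8"
        )
        np.savez(directory / "weights.npz", **self.state_dict())


ENCODERS = {"cnn": CnnEncoder, "lstm": LstmEncoder, "transformer": TransformerEncoder}


def build_encoder(
    name: str, vocab: Vocab, config: EncoderConfig, seed: int = 0
) -> _EncoderBase:
    if name not in ENCODERS:
        raise ValueError(f"unknown encoder {name!r}; choose from {sorted(ENCODERS)}")
    return ENCODERS[name](vocab, config, seed=seed)
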