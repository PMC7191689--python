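"""Gated fusion of distributed and handcrafted pair representations.

Both representations are projected into a common space with tanh
activations; a learned sigmoid gate blends them componentwise::

    d_norm = tanh(W_d . D + b_d)
    o_norm = tanh(W_o . O + b_o)
    f      = sigmoid(W_f . [d_norm, o_norm] + b_f)
    r      = f * d_norm + (1 - f) * o_norm

The module exposes the closed-form operations (:func:`fuse`,
:func:`concat_representations`, :func:`predict_score`) on plain numpy arrays,
and :class:`STSModel` which trains the same computation end-to-end (with any
of the encoders, or either representation alone) against gold similarity
scores by minibatch Adam on mean squared error, early-stopping on dev Pearson.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from . import autograd as ag
from .corpus_io import Corpus, EmbeddingTable
from .encoders import EncoderConfig, PairRepresentation, Vocab, build_encoder
from .evaluation import pearson
from .onehot import (
    FEATURE_NAMES,
    FeatureVector,
    IdfModel,
    KernelParams,
    featurize_pairs,
    fit_idf,
)
from .preprocess import TokenizedPair, tokenize_pairs

logger = logging.getLogger(__name__)

__all__ = [
    "FusedRepresentation",
    "FusionParameters",
    "STSModel",
    "TrainConfig",
    "TrainResult",
    "concat_representations",
    "fuse",
    "init_fusion_parameters",
    "predict_score",
    "train",
]

MODES = ("onehot_only", "encoder_only", "concat", "gated")


# ---------------------------------------------------------------------------
# closed-form operations on numpy arrays
# ---------------------------------------------------------------------------

@dataclass
class FusionParameters:
    """Parameter set for the gate equations and the regression head.

    Matrix conventions: ``W_d`` is [d, d_D], ``W_o`` is [d, F], ``W_f`` is
    [d, 2d]; biases have length d.  ``head_w`` matches the head input
    (length d for single/gated paths, 2d for the concatenation baseline).
    """

    W_d: np.ndarray
    b_d: np.ndarray
    W_o: np.ndarray
    b_o: np.ndarray
    W_f: np.ndarray
    b_f: np.ndarray
    head_w: np.ndarray
    head_b: float

    def __post_init__(self) -> None:
        for name in ("W_d", "b_d", "W_o", "b_o", "W_f", "b_f", "head_w"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"non-finite values in {name}")
        d = self.b_d.size
        if self.b_o.size != d or self.b_f.size != d:
            raise ValueError("projection biases disagree on common dimension")
        if self.W_d.shape[0] != d or self.W_o.shape[0] != d:
            raise ValueError("projection matrices disagree on common dimension")
        if self.W_f.shape != (d, 2 * d):
            raise ValueError("gate matrix must map the 2d concatenation to d")


@dataclass
class FusedRepresentation:
    """Gate value and blended vector for one pair."""

    d_norm: np.ndarray
    o_norm: np.ndarray
    gate: np.ndarray
    r: np.ndarray


def init_fusion_parameters(
    d: int, d_D: int, n_features: int, seed: int = 0, head_dim: Optional[int] = None
) -> FusionParameters:
    """Random Glorot-style initialization of all fusion parameters."""
    rng = np.random.default_rng(seed)

    def mat(rows: int, cols: int) -> np.ndarray:
        return rng.normal(0.0, 1.0 / np.sqrt(cols), size=(rows, cols))

    head_dim = d if head_dim is None else head_dim
    return FusionParameters(
        W_d=mat(d, d_D),
        b_d=np.zeros(d),
        W_o=mat(d, n_features),
        b_o=np.zeros(d),
        W_f=mat(d, 2 * d),
        b_f=np.zeros(d),
        head_w=mat(1, head_dim)[0],
        head_b=0.0,
    )


def _as_vector(x: Union[np.ndarray, PairRepresentation, FeatureVector]) -> np.ndarray:
    if isinstance(x, PairRepresentation):
        return x.values
    if isinstance(x, FeatureVector):
        return x.values
    return np.asarray(x, dtype=float).ravel()


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60.0, 60.0)))


def fuse(
    D: Union[np.ndarray, PairRepresentation],
    O: Union[np.ndarray, FeatureVector],
    params: FusionParameters,
) -> FusedRepresentation:
    """Blend the two representations through the learned sigmoid gate."""
    D, O = _as_vector(D), _as_vector(O)
    d_norm = np.tanh(params.W_d @ D + params.b_d)
    o_norm = np.tanh(params.W_o @ O + params.b_o)
    gate = _sigmoid(params.W_f @ np.concatenate([d_norm, o_norm]) + params.b_f)
    r = gate * d_norm + (1.0 - gate) * o_norm
    for name, vec in (("d_norm", d_norm), ("o_norm", o_norm), ("gate", gate), ("r", r)):
        if not np.all(np.isfinite(vec)):
            raise FloatingPointError(
                f"non-finite {name} during fusion; parameters: {params}"
            )
    return FusedRepresentation(d_norm=d_norm, o_norm=o_norm, gate=gate, r=r)


def concat_representations(
    D: Union[np.ndarray, PairRepresentation],
    O: Union[np.ndarray, FeatureVector],
    params: FusionParameters,
) -> np.ndarray:
    """Concatenation baseline: ``[d_norm, o_norm]`` of length 2d."""
    fused = fuse(D, O, params)
    return np.concatenate([fused.d_norm, fused.o_norm])


def predict_score(r: np.ndarray, params: FusionParameters) -> float:
    """Regression head: ``5 * sigmoid(head_w . r + head_b)``, inside (0, 5)."""
    r = np.asarray(r, dtype=float).ravel()
    return float(5.0 * _sigmoid(params.head_w @ r + params.head_b))


# ---------------------------------------------------------------------------
# trainable end-to-end model
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    """Everything the training loop needs; all defaults are desk-scale."""

    mode: str = "gated"
    encoder: str = "cnn"
    common_dim: int = 64
    lr: float = 1e-3
    batch_size: int = 32
    max_epochs: int = 200
    patience: int = 10
    seed: int = 0
    feature_embedding_dim: int = 32
    kernel: KernelParams = field(default_factory=KernelParams)
    encoder_config: EncoderConfig = field(default_factory=EncoderConfig)

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.encoder not in ("cnn", "lstm", "transformer"):
            raise ValueError(f"unknown encoder {self.encoder!r}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "TrainConfig":
        data = dict(data)
        if isinstance(data.get("kernel"), dict):
            data["kernel"] = KernelParams(**data["kernel"])
        if isinstance(data.get("encoder_config"), dict):
            ec = dict(data["encoder_config"])
            if "cnn_filter_widths" in ec:
                ec["cnn_filter_widths"] = tuple(ec["cnn_filter_widths"])
            data["encoder_config"] = EncoderConfig(**ec)
        return cls(**data)


@dataclass
class TrainResult:
    model: "STSModel"
    history: List[Dict[str, float]]
    best_epoch: int
    best_dev_pearson: Optional[float]


class STSModel:
    """End-to-end similarity regressor over any representation mode."""

    def __init__(
        self,
        config: TrainConfig,
        idf: IdfModel,
        feature_mean: np.ndarray,
        feature_std: np.ndarray,
        feature_table: EmbeddingTable,
        vocab: Optional[Vocab],
    ) -> None:
        self.config = config
        self.idf = idf
        self.feature_mean = feature_mean
        self.feature_std = feature_std
        self.feature_table = feature_table
        self.vocab = vocab
        self.encoder = None
        self._needs_encoder = config.mode != "onehot_only"
        if self._needs_encoder:
            assert vocab is not None
            self.encoder = build_encoder(
                config.encoder, vocab, config.encoder_config, seed=config.seed + 1
            )
        rng = np.random.default_rng(config.seed + 2)
        d = config.common_dim
        n_feat = len(FEATURE_NAMES)
        d_D = self.encoder.output_dim if self.encoder else 1
        self.fusion: Dict[str, ag.Tensor] = {
            "Wd": ag.parameter(rng, d_D, d),
            "bd": ag.Tensor(np.zeros(d), requires_grad=True),
            "Wo": ag.parameter(rng, n_feat, d),
            "bo": ag.Tensor(np.zeros(d), requires_grad=True),
            "Wf": ag.parameter(rng, 2 * d, d),
            "bf": ag.Tensor(np.zeros(d), requires_grad=True),
            "head_w": ag.parameter(rng, self._head_dim(), 1),
            "head_b": ag.Tensor(np.zeros(1), requires_grad=True),
        }

    def _head_dim(self) -> int:
        return 2 * self.config.common_dim if self.config.mode == "concat" \
            else self.config.common_dim

    # -- forward ----------------------------------------------------------
    def forward(
        self, pairs: Sequence[TokenizedPair], features: np.ndarray
    ) -> ag.Tensor:
        """Predicted scores for a batch, as a [B] tensor in (0, 5)."""
        mode = self.config.mode
        O = ag.Tensor((features - self.feature_mean) / self.feature_std)
        o_norm = (O @ self.fusion["Wo"] + self.fusion["bo"]).tanh()
        if mode == "onehot_only":
            head_in = o_norm
        else:
            assert self.encoder is not None
            D = self.encoder.encode_batch(pairs)
            d_norm = (D @ self.fusion["Wd"] + self.fusion["bd"]).tanh()
            if mode == "encoder_only":
                head_in = d_norm
            elif mode == "concat":
                head_in = ag.concat([d_norm, o_norm], axis=1)
            else:  # gated
                gate_in = ag.concat([d_norm, o_norm], axis=1)
                gate = (gate_in @ self.fusion["Wf"] + self.fusion["bf"]).sigmoid()
                head_in = gate * d_norm + (1.0 - gate) * o_norm
        logits = head_in @ self.fusion["head_w"] + self.fusion["head_b"]
        scores = logits.sigmoid() * 5.0
        return scores.reshape(len(pairs))

    def parameters(self) -> List[ag.Tensor]:
        params = list(self.fusion.values())
        if self.encoder is not None:
            params += self.encoder.parameters()
        return params

    # -- feature pipeline -------------------------------------------------
    def featurize(self, pairs: Sequence[TokenizedPair]) -> np.ndarray:
        return featurize_pairs(pairs, self.idf, self.feature_table, self.config.kernel)

    def predict_tokenized(self, pairs: Sequence[TokenizedPair]) -> np.ndarray:
        feats = self.featurize(pairs)
        out = np.empty(len(pairs))
        bs = max(self.config.batch_size, 1)
        for lo in range(0, len(pairs), bs):
            batch = pairs[lo : lo + bs]
            out[lo : lo + bs] = self.forward(batch, feats[lo : lo + bs]).data
        return out

    def predict(self, corpus: Corpus) -> np.ndarray:
        """Predict similarity scores for raw sentence pairs."""
        return self.predict_tokenized(tokenize_pairs(list(corpus)))

    # -- persistence ------------------------------------------------------
    def state_dict(self) -> Dict[str, np.ndarray]:
        state = {f"fusion/{k}": v.data.copy() for k, v in self.fusion.items()}
        if self.encoder is not None:
            state.update(
                {f"encoder/{k}": v for k, v in self.encoder.state_dict().items()}
            )
        return state

    def load_state(self, state: Dict[str, np.ndarray]) -> None:
        for k, v in state.items():
            scope, name = k.split("/", 1)
            if scope == "fusion":
                self.fusion[name].data = np.asarray(v, dtype=float).copy()
            elif scope == "encoder":
                assert self.encoder is not None
                self.encoder.load_state({name: v})
            else:
                raise KeyError(f"unknown state scope {scope!r}")

    def save_checkpoint(self, path: Union[str, Path]) -> None:
        """Single-archive checkpoint: parameters + config + feature pipeline."""
        meta = {
            "config": self.config.to_dict(),
            "feature_names": list(FEATURE_NAMES),
            "feature_mean": self.feature_mean.tolist(),
            "feature_std": self.feature_std.tolist(),
            "idf_doc_count": self.idf.doc_count,
            "idf_tokens": list(self.idf.df.keys()),
            "idf_counts": list(self.idf.df.values()),
            "feature_table_seed": self.feature_table.seed,
            "feature_table_dim": self.feature_table.dimension,
            "vocab": self.vocab.itos if self.vocab else None,
        }
        arrays = self.state_dict()
        arrays["__meta__"] = np.frombuffer(
            json.dumps(meta).encode("utf-8"), dtype=np.uint8
        )
        np.savez(path, **arrays)

    @classmethod
    def load_checkpoint(cls, path: Union[str, Path]) -> "STSModel":
        with np.load(path) as bundle:
            meta = json.loads(bytes(bundle["__meta__"]).decode("utf-8"))
            arrays = {k: bundle[k] for k in bundle.files if k != "__meta__"}
        config = TrainConfig.from_dict(meta["config"])
        idf = IdfModel(
            doc_count=meta["idf_doc_count"],
            df=dict(zip(meta["idf_tokens"], meta["idf_counts"])),
        )
        table = EmbeddingTable.random(
            meta["feature_table_dim"], seed=meta["feature_table_seed"]
        )
        vocab = None
        if meta["vocab"] is not None:
            vocab = Vocab([])
            vocab.itos = list(meta["vocab"])
            vocab.stoi = {t: i for i, t in enumerate(vocab.itos)}
        model = cls(
            config,
            idf,
            np.asarray(meta["feature_mean"]),
            np.asarray(meta["feature_std"]),
            table,
            vocab,
        )
        model.load_state(arrays)
        return model


def train(
    train_corpus: Corpus,
    dev_corpus: Optional[Corpus],
    config: TrainConfig,
    embeddings: Optional[EmbeddingTable] = None,
) -> TrainResult:
    """Fit an :class:`STSModel` by minibatch Adam on mean squared error.

    Early-stops on dev Pearson with the configured patience and returns the
    best-dev checkpoint; with an empty/absent dev set a fixed number of
    epochs is run instead.  Deterministic given ``config.seed``.
    """
    train_pairs = tokenize_pairs(list(train_corpus))
    gold = train_corpus.scores
    idf = fit_idf(train_pairs)
    feature_table = embeddings or EmbeddingTable.random(
        config.feature_embedding_dim, seed=config.seed + 3
    )
    raw_feats = featurize_pairs(train_pairs, idf, feature_table, config.kernel)
    mean = raw_feats.mean(axis=0)
    std = np.maximum(raw_feats.std(axis=0), 1e-8)
    vocab = Vocab.from_pairs(train_pairs) if config.mode != "onehot_only" else None

    model = STSModel(config, idf, mean, std, feature_table, vocab)
    if embeddings is not None and model.encoder is not None and \
            embeddings.dimension == config.encoder_config.embedding_dim:
        model.encoder.init_embeddings(embeddings)

    dev_pairs: List[TokenizedPair] = []
    dev_gold = np.empty(0)
    if dev_corpus is not None and len(dev_corpus) > 0:
        dev_pairs = tokenize_pairs(list(dev_corpus))
        dev_gold = dev_corpus.scores
    use_early_stop = len(dev_pairs) >= 2
    if not use_early_stop:
        logger.warning("dev set too small for early stopping; fixed epoch count")

    optimizer = ag.Adam(model.parameters(), lr=config.lr)
    rng = np.random.default_rng(config.seed)
    n = len(train_pairs)
    bs = min(config.batch_size, n)
    history: List[Dict[str, float]] = []
    best_state: Optional[Dict[str, np.ndarray]] = None
    best_pearson = -np.inf
    best_epoch = -1
    stale = 0

    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for lo in range(0, n, bs):
            idx = order[lo : lo + bs]
            batch = [train_pairs[i] for i in idx]
            preds = model.forward(batch, raw_feats[idx])
            err = preds - gold[idx]
            loss = (err * err).mean()
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}; lr={config.lr}, "
                    f"mode={config.mode}, encoder={config.encoder}"
                )
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            epoch_loss += float(loss.data) * len(idx)
        epoch_loss /= n
        record: Dict[str, float] = {"epoch": epoch, "train_mse": epoch_loss}
        if use_early_stop:
            dev_pred = model.predict_tokenized(dev_pairs)
            dev_r = pearson(dev_pred, dev_gold)
            record["dev_pearson"] = np.nan if dev_r is None else dev_r
            history.append(record)
            if dev_r is not None and dev_r > best_pearson:
                best_pearson = dev_r
                best_epoch = epoch
                best_state = model.state_dict()
                stale = 0
            else:
                stale += 1
                if stale > config.patience:
                    logger.info("early stop at epoch %d (best %d)", epoch, best_epoch)
                    break
        else:
            history.append(record)
    if best_state is not None:
        model.load_state(best_state)
    return TrainResult(
        model=model,
        history=history,
        best_epoch=best_epoch,
        best_dev_pearson=None if not use_early_stop else float(best_pearson),
    )
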