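"""Sentence-pair corpora, embedding tables and the stratified train/dev split.

Corpus files are UTF-8 TSV without a header: ``sentence1<TAB>sentence2`` with
an optional third column holding the reference similarity in [0, 5].
Embedding tables are read from word2vec text or binary layouts.
"""

from __future__ import annotations

import hashlib
import logging
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterator, List, Optional, Sequence, Tuple, Union

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Corpus",
    "CorpusFormatError",
    "EmbeddingTable",
    "SentencePair",
    "load_embeddings",
    "read_pairs",
    "stratified_split",
    "write_pairs",
    "write_predictions",
]


class CorpusFormatError(ValueError):
    """A corpus or embedding file violates its format contract."""


@dataclass
class SentencePair:
    """Two raw sentences with an optional reference similarity in [0, 5]."""

    pair_id: str
    s1: str
    s2: str
    gold: Optional[float] = None
    #: original score text, preserved so written files round-trip exactly
    gold_text: Optional[str] = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.s1 or not self.s2:
            raise ValueError(f"pair {self.pair_id}: sentences must be non-empty")
        if self.gold is not None and not (0.0 <= self.gold <= 5.0):
            raise ValueError(
                f"pair {self.pair_id}: score {self.gold} outside [0, 5]"
            )


@dataclass
class Corpus:
    """Ordered collection of :class:`SentencePair` with unique ids."""

    pairs: List[SentencePair]
    provenance: str = "unknown"

    def __post_init__(self) -> None:
        ids = [p.pair_id for p in self.pairs]
        if len(set(ids)) != len(ids):
            raise ValueError("pair_ids are not unique within the corpus")

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self) -> Iterator[SentencePair]:
        return iter(self.pairs)

    def __getitem__(self, i: int) -> SentencePair:
        return self.pairs[i]

    @property
    def scores(self) -> np.ndarray:
        """Gold scores as an array; raises if any pair is unscored."""
        if any(p.gold is None for p in self.pairs):
            raise ValueError("corpus contains unscored pairs")
        return np.asarray([p.gold for p in self.pairs], dtype=float)


def read_pairs(path: Union[str, Path], has_scores: bool = True) -> Corpus:
    """Read a sentence-pair TSV.

    Each line must have two tab-separated sentences, plus a score column when
    *has_scores* is true.  Line numbers are 1-based in error messages.
    """
    path = Path(path)
    expected = 3 if has_scores else 2
    pairs: List[SentencePair] = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != expected:
                raise CorpusFormatError(
                    f"{path}:{lineno}: expected {expected} tab-separated "
                    f"fields, got {len(fields)}"
                )
            gold: Optional[float] = None
            gold_text: Optional[str] = None
            if has_scores:
                gold_text = fields[2]
                try:
                    gold = float(gold_text)
                except ValueError as exc:
                    raise CorpusFormatError(
                        f"{path}:{lineno}: unparseable score {gold_text!r}"
                    ) from exc
                if not (0.0 <= gold <= 5.0):
                    raise CorpusFormatError(
                        f"{path}:{lineno}: score {gold} outside [0, 5]"
                    )
            try:
                pairs.append(
                    SentencePair(
                        pair_id=str(lineno),
                        s1=fields[0],
                        s2=fields[1],
                        gold=gold,
                        gold_text=gold_text,
                    )
                )
            except ValueError as exc:
                raise CorpusFormatError(f"{path}:{lineno}: {exc}") from exc
    return Corpus(pairs=pairs, provenance=str(path))


def _format_score(pair: SentencePair) -> str:
    if pair.gold_text is not None:
        return pair.gold_text
    assert pair.gold is not None
    return format(pair.gold, ".12g")


def write_pairs(corpus: Corpus, path: Union[str, Path]) -> None:
    """Write a corpus back to TSV (inverse of :func:`read_pairs`)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for p in corpus:
            if p.gold is None:
                fh.write(f"{p.s1}\t{p.s2}\n")
            else:
                fh.write(f"{p.s1}\t{p.s2}\t{_format_score(p)}\n")


def write_predictions(
    corpus: Corpus, predictions: Sequence[float], path: Union[str, Path]
) -> None:
    """Write the input TSV columns with a prediction column appended."""
    if len(predictions) != len(corpus):
        raise ValueError("prediction count does not match corpus size")
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for p, score in zip(corpus, predictions):
            cols = [p.s1, p.s2]
            if p.gold is not None:
                cols.append(_format_score(p))
            cols.append(f"{float(score):.4f}")
            fh.write("\t".join(cols) + "\n")


def score_interval(gold: float) -> int:
    """Index of the unit score interval: [0,1),...,[3,4),[4,5]."""
    return min(int(np.floor(gold)), 4)


def stratified_split(
    corpus: Corpus, dev_fraction: float = 0.2, seed: int = 0
) -> Tuple[Corpus, Corpus]:
    """Split into train/dev, stratified over the five unit score intervals.

    Within each stratum, ``round(dev_fraction * size)`` pairs go to dev.
    Deterministic given *seed*; original corpus order is preserved inside
    each output.
    """
    if not (0.0 < dev_fraction < 1.0):
        raise ValueError("dev_fraction must lie in (0, 1)")
    if any(p.gold is None for p in corpus):
        raise ValueError("stratified_split requires every pair to be scored")
    rng = np.random.default_rng(seed)
    strata: Dict[int, List[int]] = {k: [] for k in range(5)}
    for idx, pair in enumerate(corpus):
        strata[score_interval(pair.gold)].append(idx)  # type: ignore[arg-type]
    dev_idx: set = set()
    for indices in strata.values():
        if not indices:
            continue
        n_dev = int(np.floor(dev_fraction * len(indices) + 0.5))
        chosen = rng.permutation(len(indices))[:n_dev]
        dev_idx.update(indices[i] for i in chosen)
    if not dev_idx:
        logger.warning("stratified_split produced an empty dev set")
    train = [p for i, p in enumerate(corpus) if i not in dev_idx]
    dev = [p for i, p in enumerate(corpus) if i in dev_idx]
    return (
        Corpus(train, provenance=f"{corpus.provenance}#train"),
        Corpus(dev, provenance=f"{corpus.provenance}#dev"),
    )


class EmbeddingTable:
    """Token -> dense vector lookup with an out-of-vocabulary policy.

    ``oov_policy`` is ``"zero"`` (unseen tokens map to the zero vector) or
    ``"random-fixed-seed"`` (unseen tokens map to a vector drawn from a
    generator seeded by a stable hash of the token, so lookups are
    reproducible across processes).
    """

    POLICIES = ("zero", "random-fixed-seed")

    def __init__(
        self,
        dimension: int,
        vectors: Optional[Dict[str, np.ndarray]] = None,
        oov_policy: str = "zero",
        seed: int = 0,
    ) -> None:
        if dimension <= 0:
            raise ValueError("dimension must be positive")
        if oov_policy not in self.POLICIES:
            raise ValueError(f"unknown oov_policy {oov_policy!r}")
        self.dimension = int(dimension)
        self.vectors: Dict[str, np.ndarray] = {}
        self.oov_policy = oov_policy
        self.seed = int(seed)
        for token, vec in (vectors or {}).items():
            vec = np.asarray(vec, dtype=float)
            if vec.shape != (self.dimension,):
                raise CorpusFormatError(
                    f"vector for {token!r} has length {vec.size}, "
                    f"expected {self.dimension}"
                )
            self.vectors[token] = vec

    @classmethod
    def random(cls, dimension: int, seed: int = 0) -> "EmbeddingTable":
        """Empty table whose every lookup is a reproducible random vector."""
        return cls(dimension, {}, oov_policy="random-fixed-seed", seed=seed)

    def __len__(self) -> int:
        return len(self.vectors)

    def __contains__(self, token: str) -> bool:
        return token in self.vectors

    def _oov_vector(self, token: str) -> np.ndarray:
        if self.oov_policy == "zero":
            return np.zeros(self.dimension)
        digest = hashlib.blake2b(
            token.encode("utf-8"), digest_size=8, key=str(self.seed).encode()
        ).digest()
        rng = np.random.default_rng(int.from_bytes(digest, "little"))
        return rng.normal(0.0, 1.0, size=self.dimension) / np.sqrt(self.dimension)

    def lookup(self, token: str) -> np.ndarray:
        vec = self.vectors.get(token)
        if vec is None:
            return self._oov_vector(token)
        return vec

    def sentence_vector(self, tokens: Sequence[str]) -> np.ndarray:
        """Mean of the tokens' vectors; zero vector for an empty sentence."""
        if not tokens:
            return np.zeros(self.dimension)
        return np.mean([self.lookup(t) for t in tokens], axis=0)


def _load_text_embeddings(path: Path) -> Tuple[int, Dict[str, np.ndarray]]:
    vectors: Dict[str, np.ndarray] = {}
    dimension: Optional[int] = None
    with path.open("r", encoding="utf-8") as fh:
        first = fh.readline()
        parts = first.rstrip("\n").split(" ")
        # word2vec text files open with a "count dim" header; plain GloVe-style
        # files start directly with a token row.
        if len(parts) == 2 and all(p.isdigit() for p in parts):
            dimension = int(parts[1])
        else:
            token, vec = parts[0], np.asarray(parts[1:], dtype=float)
            dimension = vec.size
            vectors[token] = vec
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split(" ")
            if len(parts) < 2:
                continue
            token = parts[0]
            try:
                vec = np.asarray(parts[1:], dtype=float)
            except ValueError as exc:
                raise CorpusFormatError(f"{path}:{lineno}: bad vector") from exc
            if vec.size != dimension:
                raise CorpusFormatError(
                    f"{path}:{lineno}: dimension {vec.size} != {dimension}"
                )
            vectors[token] = vec
    if dimension is None or not vectors:
        raise CorpusFormatError(f"{path}: no vectors found")
    return dimension, vectors


def _load_binary_embeddings(path: Path) -> Tuple[int, Dict[str, np.ndarray]]:
    vectors: Dict[str, np.ndarray] = {}
    with path.open("rb") as fh:
        header = fh.readline().decode("utf-8").split()
        if len(header) != 2:
            raise CorpusFormatError(f"{path}: malformed word2vec binary header")
        count, dimension = int(header[0]), int(header[1])
        vec_bytes = 4 * dimension
        for _ in range(count):
            chars = []
            while True:
                ch = fh.read(1)
                if not ch:
                    raise CorpusFormatError(f"{path}: truncated binary file")
                if ch == b" ":
                    break
                if ch != b"\n":
                    chars.append(ch)
            token = b"".join(chars).decode("utf-8")
            buf = fh.read(vec_bytes)
            if len(buf) != vec_bytes:
                raise CorpusFormatError(f"{path}: truncated vector for {token!r}")
            vectors[token] = np.asarray(
                struct.unpack(f"<{dimension}f", buf), dtype=float
            )
    return dimension, vectors


def load_embeddings(
    path: Union[str, Path],
    fmt: str = "text",
    oov_policy: str = "zero",
    seed: int = 0,
) -> EmbeddingTable:
    """Load a word2vec-layout embedding table (``fmt`` in {"text", "binary"})."""
    path = Path(path)
    if fmt == "text":
        dimension, vectors = _load_text_embeddings(path)
    elif fmt == "binary":
        dimension, vectors = _load_binary_embeddings(path)
    else:
        raise ValueError(f"unknown embedding format {fmt!r}")
    return EmbeddingTable(dimension, vectors, oov_policy=oov_policy, seed=seed)
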