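"""Handcrafted ("one-hot") sentence-pair features.

The feature vector has a fixed 17-slot layout::

    len1, len2, len_absdiff,
    idf1, idf2, idf_absdiff,
    ngo1, ngo2, ngo3,
    cosine, manhattan, euclidean, chebyshev,
    polynomial, rbf, laplacian, sigmoid

Lengths and inverse-document-frequency aggregates are per-sentence values;
n-gram overlaps are Dice-style coefficients over distinct n-gram sets; the
eight tail slots are distances/kernels between the two sentences' averaged
embedding vectors.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np

from .corpus_io import EmbeddingTable
from .preprocess import TokenizedPair

logger = logging.getLogger(__name__)

__all__ = [
    "FEATURE_NAMES",
    "FeatureVector",
    "IdfModel",
    "KernelParams",
    "build_onehot",
    "featurize_pairs",
    "fit_idf",
    "ngram_overlap",
    "pair_similarities",
]

SIMILARITY_NAMES: Tuple[str, ...] = (
    "cosine",
    "manhattan",
    "euclidean",
    "chebyshev",
    "polynomial",
    "rbf",
    "laplacian",
    "sigmoid",
)

FEATURE_NAMES: Tuple[str, ...] = (
    "len1",
    "len2",
    "len_absdiff",
    "idf1",
    "idf2",
    "idf_absdiff",
    "ngo1",
    "ngo2",
    "ngo3",
) + SIMILARITY_NAMES


@dataclass
class FeatureVector:
    """Fixed-length handcrafted representation of a sentence pair."""

    values: np.ndarray
    names: Tuple[str, ...] = FEATURE_NAMES

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.names),):
            raise ValueError("feature vector length does not match names")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite feature value")

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class IdfModel:
    """Smoothed inverse document frequency fitted on training sentences.

    Each sentence (not pair) counts as one document;
    ``idf(w) = ln(N / (1 + df(w)))`` so unseen tokens stay finite.
    """

    doc_count: int
    df: Dict[str, int] = field(default_factory=dict)

    def idf(self, token: str) -> float:
        return math.log(self.doc_count / (1 + self.df.get(token, 0)))

    def sentence_idf(self, tokens: Sequence[str], aggregate: str = "mean") -> float:
        if not tokens:
            return 0.0
        vals = [self.idf(t) for t in tokens]
        if aggregate == "mean":
            return float(np.mean(vals))
        if aggregate == "sum":
            return float(np.sum(vals))
        raise ValueError(f"unknown aggregate {aggregate!r}")


def fit_idf(train: Iterable[TokenizedPair]) -> IdfModel:
    """Fit document frequencies on the training pairs' sentences."""
    df: Dict[str, int] = {}
    n_docs = 0
    for pair in train:
        for tokens in (pair.tokens1, pair.tokens2):
            n_docs += 1
            for token in set(tokens):
                df[token] = df.get(token, 0) + 1
    if n_docs == 0:
        raise ValueError("cannot fit IDF on an empty collection")
    return IdfModel(doc_count=n_docs, df=df)


def _ngram_set(tokens: Sequence[str], n: int) -> set:
    return {tuple(tokens[i : i + n]) for i in range(len(tokens) - n + 1)}


def ngram_overlap(tokens1: Sequence[str], tokens2: Sequence[str], n: int) -> float:
    """Dice-style overlap 2|G1 ∩ G2| / (|G1| + |G2|) of distinct n-gram sets.

    Returns 0.0 when both sentences are shorter than *n* (both sets empty).
    """
    if n not in (1, 2, 3):
        raise ValueError(f"n must be 1, 2 or 3, got {n}")
    g1, g2 = _ngram_set(tokens1, n), _ngram_set(tokens2, n)
    denom = len(g1) + len(g2)
    if denom == 0:
        return 0.0
    return 2.0 * len(g1 & g2) / denom


@dataclass
class KernelParams:
    """Hyperparameters for the kernel similarities.

    ``gamma=None`` means 1/dimension, the usual library default.
    """

    gamma: float | None = None
    coef0: float = 1.0
    degree: int = 3

    def resolved_gamma(self, dimension: int) -> float:
        return 1.0 / dimension if self.gamma is None else self.gamma


def pair_similarities(
    tokens1: Sequence[str],
    tokens2: Sequence[str],
    emb: EmbeddingTable,
    params: KernelParams | None = None,
) -> Dict[str, float]:
    """Eight distances/kernels between averaged-embedding sentence vectors.

    Cosine is defined as 0 when either vector is all-zero (logged once per
    call site at debug level).
    """
    params = params or KernelParams()
    v1 = emb.sentence_vector(tokens1)
    v2 = emb.sentence_vector(tokens2)
    gamma = params.resolved_gamma(emb.dimension)
    diff = v1 - v2
    l1 = float(np.sum(np.abs(diff)))
    l2sq = float(np.dot(diff, diff))
    dot = float(np.dot(v1, v2))
    n1, n2 = float(np.linalg.norm(v1)), float(np.linalg.norm(v2))
    if n1 == 0.0 or n2 == 0.0:
        logger.debug("all-zero sentence vector; cosine set to 0 by convention")
        cosine = 0.0
    else:
        cosine = dot / (n1 * n2)
    return {
        "cosine": cosine,
        "manhattan": l1,
        "euclidean": math.sqrt(l2sq),
        "chebyshev": float(np.max(np.abs(diff))) if diff.size else 0.0,
        "polynomial": (gamma * dot + params.coef0) ** params.degree,
        "rbf": math.exp(-gamma * l2sq),
        "laplacian": math.exp(-gamma * l1),
        "sigmoid": math.tanh(gamma * dot + params.coef0),
    }


def build_onehot(
    pair: TokenizedPair,
    idf: IdfModel,
    emb: EmbeddingTable,
    params: KernelParams | None = None,
    idf_aggregate: str = "mean",
) -> FeatureVector:
    """Assemble the full 17-slot handcrafted feature vector for one pair."""
    t1, t2 = pair.tokens1, pair.tokens2
    idf1 = idf.sentence_idf(t1, idf_aggregate)
    idf2 = idf.sentence_idf(t2, idf_aggregate)
    sims = pair_similarities(t1, t2, emb, params)
    values = [
        float(len(t1)),
        float(len(t2)),
        float(abs(len(t1) - len(t2))),
        idf1,
        idf2,
        abs(idf1 - idf2),
        ngram_overlap(t1, t2, 1),
        ngram_overlap(t1, t2, 2),
        ngram_overlap(t1, t2, 3),
    ] + [sims[name] for name in SIMILARITY_NAMES]
    return FeatureVector(np.asarray(values))


def featurize_pairs(
    pairs: Sequence[TokenizedPair],
    idf: IdfModel,
    emb: EmbeddingTable,
    params: KernelParams | None = None,
) -> np.ndarray:
    """Feature matrix of shape (n_pairs, 17)."""
    return np.vstack([build_onehot(p, idf, emb, params).values for p in pairs])
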