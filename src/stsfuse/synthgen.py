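"""Synthetic scored sentence-pair corpora with controllable overlap structure.

The generator draws a target score interval, turns it into a token keep
probability, perturbs a randomly sampled sentence into its partner, and sets
the gold score from the *realized* unigram overlap (plus optional jitter), so
that downstream feature extractors can recover the signal near-perfectly.

The vocabulary is styled on clinical tokens purely so token statistics look
plausible; every vocabulary entry is a fixed point of
:func:`stsfuse.preprocess.normalize`, which keeps the generated overlap
observable after preprocessing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .corpus_io import Corpus, SentencePair
from .onehot import ngram_overlap

__all__ = ["CLINICAL_VOCAB", "GeneratorConfig", "generate", "worked_fixture"]

CLINICAL_VOCAB: Tuple[str, ...] = (
    "patient", "nurse", "visit", "chest", "pain", "fever", "cough", "wound",
    "care", "plan", "review", "system", "negative", "positive", "history",
    "exam", "blood", "pressure", "heart", "rate", "lung", "clear", "left",
    "right", "knee", "hip", "shoulder", "fracture", "swelling", "tenderness",
    "medication", "dose", "daily", "oral", "tablet", "insulin", "glucose",
    "level", "stable", "discharge", "home", "follow", "clinic", "week",
    "month", "morning", "evening", "mild", "moderate", "severe", "acute",
    "chronic", "infection", "antibiotic", "therapy", "physical", "walker",
    "assist", "ambulate", "deny", "diagnosis", "abscess", "edema", "rash",
    "nausea", "headache", "fatigue", "anxiety", "screen", "counsel",
    "educate", "instruction", "barrier", "preference", "listen",
    "interpreter", "spouse", "family", "transport", "oxygen", "saturation",
    "breath", "sound", "abdomen", "soft", "tender", "bowel", "normal", "lab",
    "result", "pending", "culture", "urine", "kidney", "liver", "function",
    "baseline", "monitor", "schedule", "appointment", "surgery", "incision",
    "heal", "suture", "removal", "balance", "strength", "range", "motion",
    "exercise", "caregiver", "report", "symptom", "onset", "duration",
    "rest", "activity", "diet", "fluid", "intake", "output", "weight",
    "gain", "appetite", "sleep", "alert", "oriented", "skin", "warm", "dry",
    "intact", "wheelchair", "cane", "fall", "risk", "precaution", "allergy",
    "reaction", "refill", "pharmacy", "injection", "site", "arm", "leg",
    "foot", "ankle", "wrist", "elbow", "spine", "neck", "joint", "muscle",
)


@dataclass
class GeneratorConfig:
    """Knobs for :func:`generate`.

    ``interval_weights`` is the target fraction of pairs per unit score
    interval; ``noise_sd`` jitters the gold score around the overlap-derived
    value; ``fixed_overlap`` (testing aid) forces the keep probability;
    ``replacement_vocab`` supplies the tokens used for substitutions
    (defaults to the main vocabulary).
    """

    n_pairs: int = 1000
    vocab_size: int = 80
    sentence_length: Tuple[int, int] = (6, 14)
    interval_weights: Tuple[float, ...] = (0.2, 0.2, 0.2, 0.2, 0.2)
    noise_sd: float = 0.2
    seed: int = 0
    fixed_overlap: Optional[float] = None
    replacement_vocab: Optional[Tuple[str, ...]] = None

    def __post_init__(self) -> None:
        if self.n_pairs <= 0:
            raise ValueError("n_pairs must be positive")
        if not (1 <= self.vocab_size <= len(CLINICAL_VOCAB)):
            raise ValueError(
                f"vocab_size must be in [1, {len(CLINICAL_VOCAB)}]"
            )
        lo, hi = self.sentence_length
        if lo < 1 or hi < lo:
            raise ValueError(f"infeasible sentence length range ({lo}, {hi})")
        if hi > self.vocab_size:
            raise ValueError(
                "infeasible sentence length range: sentences are sampled "
                f"without replacement, so max length {hi} needs vocab_size >= {hi}"
            )
        w = np.asarray(self.interval_weights, dtype=float)
        if w.size != 5 or np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError(
                "interval_weights must be 5 non-negative reals summing to 1"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def _fresh_tokens(
    n: int, forbidden: set, pool: Sequence[str], rng: np.random.Generator
) -> List[str]:
    """Draw *n* substitution tokens, avoiding *forbidden* when possible."""
    candidates = [t for t in pool if t not in forbidden]
    if len(candidates) >= n:
        return [str(t) for t in rng.choice(candidates, size=n, replace=False)]
    if candidates:
        return [str(t) for t in rng.choice(candidates, size=n, replace=True)]
    return [str(t) for t in rng.choice(list(pool), size=n, replace=True)]


def _perturb(
    tokens: List[str],
    keep_prob: float,
    pool: Sequence[str],
    rng: np.random.Generator,
) -> List[str]:
    """Keep a round(keep_prob * len) subset of tokens in place; every other
    token is replaced, or deleted with a fresh token inserted elsewhere, so
    the realized distinct-unigram overlap tracks *keep_prob* closely."""
    u = len(tokens)
    k = int(round(keep_prob * u))
    keep = set(rng.choice(u, size=k, replace=False)) if k else set()
    fresh = _fresh_tokens(u - k, set(tokens), pool, rng)
    out: List[str] = []
    inserts: List[str] = []
    fi = 0
    for pos, tok in enumerate(tokens):
        if pos in keep:
            out.append(tok)
            continue
        if rng.random() < 1.0 / 3.0:  # delete here, insert elsewhere
            inserts.append(fresh[fi])
        else:  # replace in place
            out.append(fresh[fi])
        fi += 1
    for tok in inserts:
        out.insert(int(rng.integers(len(out) + 1)), tok)
    if not out:
        out.append(fresh[0] if fresh else str(rng.choice(list(pool))))
    return out


def generate(config: GeneratorConfig) -> Corpus:
    """Generate a scored synthetic corpus; byte-deterministic given the seed."""
    rng = np.random.default_rng(config.seed)
    vocab = list(CLINICAL_VOCAB[: config.vocab_size])
    pool = list(config.replacement_vocab) if config.replacement_vocab else vocab
    lo, hi = config.sentence_length
    weights = np.asarray(config.interval_weights, dtype=float)
    weights = weights / weights.sum()
    pairs: List[SentencePair] = []
    for i in range(config.n_pairs):
        if config.fixed_overlap is not None:
            keep = float(config.fixed_overlap)
        else:
            interval = int(rng.choice(5, p=weights))
            keep = float(rng.uniform(interval, interval + 1)) / 5.0
        length = int(rng.integers(lo, hi + 1))
        # distinct tokens keep the realized unigram overlap on target
        t1 = [str(t) for t in rng.choice(vocab, size=length, replace=False)]
        t2 = _perturb(t1, keep, pool, rng)
        overlap = ngram_overlap(t1, t2, 1)
        gold = 5.0 * overlap
        if config.noise_sd > 0:
            gold += float(rng.normal(0.0, config.noise_sd))
        gold = float(np.clip(gold, 0.0, 5.0))
        pairs.append(
            SentencePair(
                pair_id=f"synth-{i:05d}",
                s1=" ".join(t1),
                s2=" ".join(t2),
                gold=gold,
            )
        )
    return Corpus(pairs=pairs, provenance="synthetic")


# The six annotated example pairs with integer scores 0..5, kept verbatim as
# a tiny unit-test corpus (sentences are already in normalized form).
_FIXTURE_ROWS = [
    (
        0,
        "discus necessity member healthcare team male female participate procedure",
        "report represent interpretation original data trace store electronic "
        "record esophageal laboratory",
    ),
    (
        1,
        "mother blood type o + hepatitis b negative hiv negative found gb positive",
        "patient undergone genetic test found brca1 2 negative well bart negative",
    ),
    (
        2,
        "patient discharge home ambulate without assistance discharge "
        "instruction give patient",
        "patient left without see ambulate without assistance family drive "
        "accompany husband wife",
    ),
    (
        3,
        "negative cardiovascular review system historian denies chest pain "
        "dyspnea exertion",
        "negative cardiovascular review system historian denies chest pain "
        "diaphoresis syncope palpitation",
    ),
    (
        4,
        "patient education ready learn apparent learn barrier identify learn "
        "preference include listen",
        "assistance somali interpreter ready learn apparent learn barrier "
        "identify learn preference include listen",
    ),
    (
        5,
        "nurse visit ten minute half spent counsel point test",
        "nurse visit ten minute half spent consultation point test",
    ),
]


def worked_fixture() -> Corpus:
    """Six annotated example pairs, one per integer score 0-5."""
    pairs = [
        SentencePair(pair_id=f"fixture-{score}", s1=s1, s2=s2, gold=float(score))
        for score, s1, s2 in _FIXTURE_ROWS
    ]
    return Corpus(pairs=pairs, provenance="worked-fixture")
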