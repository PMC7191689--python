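"""Sentence normalization: tokenize, lemmatize, spell out numerals, drop stopwords.

The pipeline applied by :func:`normalize` is

1. lowercase and split into alphanumeric tokens (punctuation discarded);
2. every maximal pure-digit token is expanded into English cardinal words,
   one word per token, without hyphens or "and" ("24" -> "twenty four");
3. remaining tokens are lemmatized to a base form with suffix rules
   ("instructions" -> "instruction"); tokens containing digits ("brca1")
   are left untouched;
4. stopwords are removed (after lemmatization, configurable list).

The default stopword list is deliberately minimal: it keeps content-bearing
prepositions such as "within", "without" and "every" that clinical sentences
rely on, while dropping articles, conjunctions, auxiliaries and a handful of
purely relational prepositions.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import FrozenSet, List, Optional, Sequence

__all__ = [
    "DEFAULT_STOPWORDS",
    "TokenizedPair",
    "lemmatize",
    "normalize",
    "number_to_words",
    "tokenize",
]

#: Minimal function-word list.  Keeps "within", "without", "every", "half",
#: number words, negations of clinical interest ("no", "not" are kept too).
DEFAULT_STOPWORDS: FrozenSet[str] = frozenset(
    """
    a an the and or but nor
    of in on at for to from by as into onto upon
    is are was were be been being am
    do does did done have has had having
    it its this that these those there here
    he she they them his her their our your my i we you me us
    which who whom whose what
    so such than then too very just also
    up down over out off
    will would shall should can could may might must
    """.split()
)

_TOKEN_RE = re.compile(r"[a-z0-9]+")
_DIGITS_RE = re.compile(r"^[0-9]+$")

_ONES = [
    "zero", "one", "two", "three", "four", "five", "six", "seven", "eight",
    "nine", "ten", "eleven", "twelve", "thirteen", "fourteen", "fifteen",
    "sixteen", "seventeen", "eighteen", "nineteen",
]
_TENS = [
    "", "", "twenty", "thirty", "forty", "fifty", "sixty", "seventy",
    "eighty", "ninety",
]
_SCALES = ["", "thousand", "million", "billion", "trillion"]


def _words_below_1000(n: int) -> List[str]:
    words: List[str] = []
    if n >= 100:
        words += [_ONES[n // 100], "hundred"]
        n %= 100
    if n >= 20:
        words.append(_TENS[n // 10])
        n %= 10
        if n:
            words.append(_ONES[n])
    elif n:
        words.append(_ONES[n])
    return words


def number_to_words(numeral: str) -> List[str]:
    """Expand a string of decimal digits into lowercase English cardinal words.

    No hyphens, no "and": ``"24" -> ["twenty", "four"]``,
    ``"105" -> ["one", "hundred", "five"]``.  Values with more than 15 digits
    are spelled digit by digit.

    Raises
    ------
    ValueError
        If *numeral* is empty or contains a non-digit character.
    """
    if not numeral or not _DIGITS_RE.match(numeral):
        raise ValueError(f"not a digit string: {numeral!r}")
    value = int(numeral)
    if value == 0:
        return ["zero"]
    if len(str(value)) > 15:
        return [_ONES[int(d)] for d in numeral]
    groups: List[int] = []
    while value:
        groups.append(value % 1000)
        value //= 1000
    words: List[str] = []
    for idx in range(len(groups) - 1, -1, -1):
        if groups[idx] == 0:
            continue
        words += _words_below_1000(groups[idx])
        if idx:
            words.append(_SCALES[idx])
    return words


# Irregular plurals the suffix rules would mangle.
_IRREGULAR = {
    "men": "man",
    "women": "woman",
    "children": "child",
    "feet": "foot",
    "teeth": "tooth",
    "mice": "mouse",
    "people": "person",
}

# Ordered suffix rules; first applicable wins.  Mirrors the usual English
# detachment rules for nouns.
_SUFFIX_RULES = [
    ("sses", "ss"),
    ("ches", "ch"),
    ("shes", "sh"),
    ("xes", "x"),
    ("zes", "z"),
    ("ies", "y"),
    ("s", ""),
]


def lemmatize(token: str) -> str:
    """Reduce a lowercase token to a base form with suffix rules.

    Conservative by design: tokens containing digits, tokens ending in
    "ss"/"us"/"is", and short tokens are returned unchanged, so forms such
    as "spent", "brca1" or "discus" pass through.
    """
    if any(c.isdigit() for c in token):
        return token
    if token in _IRREGULAR:
        return _IRREGULAR[token]
    if len(token) <= 3 or token.endswith(("ss", "us", "is")):
        return token
    for suffix, repl in _SUFFIX_RULES:
        if token.endswith(suffix):
            stem = token[: -len(suffix)] + repl
            if len(stem) >= 3:
                return stem
            return token
    return token


def tokenize(text: str) -> List[str]:
    """Lowercase and split into maximal alphanumeric runs."""
    return _TOKEN_RE.findall(text.lower())


def normalize(
    text: str,
    stopwords: Optional[FrozenSet[str]] = None,
) -> List[str]:
    """Normalize a raw sentence into a token list.

    Raises
    ------
    ValueError
        If *text* is empty or whitespace-only.
    """
    if not text or not text.strip():
        raise ValueError("cannot normalize an empty sentence")
    if stopwords is None:
        stopwords = DEFAULT_STOPWORDS
    out: List[str] = []
    for tok in tokenize(text):
        if _DIGITS_RE.match(tok):
            out.extend(number_to_words(tok))
            continue
        lemma = lemmatize(tok)
        if lemma not in stopwords and tok not in stopwords:
            out.append(lemma)
    return out


@dataclass
class TokenizedPair:
    """A sentence pair after normalization.

    ``tokens1``/``tokens2`` are the normalized token lists; ``gold`` is the
    optional reference similarity in [0, 5].
    """

    pair_id: str
    tokens1: List[str] = field(default_factory=list)
    tokens2: List[str] = field(default_factory=list)
    gold: Optional[float] = None


def tokenize_pairs(
    pairs: Sequence,
    stopwords: Optional[FrozenSet[str]] = None,
) -> List[TokenizedPair]:
    """Normalize a sequence of raw sentence pairs (see :mod:`stsfuse.corpus_io`)."""
    return [
        TokenizedPair(
            pair_id=p.pair_id,
            tokens1=normalize(p.s1, stopwords),
            tokens2=normalize(p.s2, stopwords),
            gold=p.gold,
        )
        for p in pairs
    ]
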