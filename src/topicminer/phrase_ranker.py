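"""Candidate-phrase ranking, a support aid for dictionary building.

Multi-word terms worth adding to a topic lexicon tend to be long noun phrases
with few function words.  The ranker enumerates contiguous token n-grams from
corpus text and orders them by (ascending stop-word fraction, descending
frequency, descending length, lexicographic); phrases made entirely of stop
words are dropped.  The output is a review list for a human dictionary
builder, not a termhood statistic.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

from .corpus import split_sentences, tokenize

__all__ = [
    "CandidatePhrase",
    "default_stopwords",
    "extract_candidates",
    "rank_candidates",
]


@dataclass(frozen=True)
class CandidatePhrase:
    tokens: tuple[str, ...]
    frequency: int
    stop_fraction: float

    @property
    def length(self) -> int:
        return len(self.tokens)

    @property
    def text(self) -> str:
        return " ".join(self.tokens)


def default_stopwords() -> frozenset[str]:
    """Standard English stop-word list shipped with the package."""
    data = resources.files("topicminer.data").joinpath("stopwords.txt").read_text()
    return frozenset(w for w in data.split() if w)


def extract_candidates(
    texts: Iterable[str], min_len: int = 2, max_len: int = 4
) -> list[CandidatePhrase]:
    """All contiguous lowercased token n-grams with min_len <= n <= max_len.

    N-grams never cross sentence boundaries.  ``stop_fraction`` is filled by
    :func:`rank_candidates` (0 here).
    """
    if not (1 <= min_len <= max_len):
        raise ValueError("require 1 <= min_len <= max_len")
    counts: Counter[tuple[str, ...]] = Counter()
    for text in texts:
        for s, e in split_sentences(text):
            sentence = text[s:e]
            tokens = [sentence[a:b].lower() for a, b in tokenize(sentence)]
            for n in range(min_len, max_len + 1):
                for i in range(len(tokens) - n + 1):
                    counts[tuple(tokens[i : i + n])] += 1
    return [
        CandidatePhrase(tokens=toks, frequency=freq, stop_fraction=0.0)
        for toks, freq in counts.items()
    ]


def rank_candidates(
    candidates: Sequence[CandidatePhrase],
    stopwords: frozenset[str] | set[str] | None = None,
) -> list[CandidatePhrase]:
    """Order candidates for manual review.

    Key: stop-word fraction ascending, then frequency descending, then length
    descending, then lexicographic.  All-stop-word phrases are removed.
    """
    if stopwords is None:
        stopwords = default_stopwords()
    scored = []
    for c in candidates:
        stop = sum(1 for t in c.tokens if t in stopwords)
        frac = stop / len(c.tokens)
        if frac >= 1.0:
            continue
        scored.append(CandidatePhrase(c.tokens, c.frequency, frac))
    scored.sort(key=lambda c: (c.stop_fraction, -c.frequency, -c.length, c.tokens))
    return scored
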