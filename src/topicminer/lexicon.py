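"""Weighted topic-term dictionaries.

A lexicon holds the hand-curated terms that define the topic of the corpus
(for the original use case: pain).  Each term carries a closed-vocabulary
category, a specificity level and a set of case-sensitive synonyms.  Terms
judged synonymous with the topic itself ("specific") weigh 2; terms merely
associated with it ("relevant") weigh 1.  Synonyms must be unambiguous:
a synonym string mapping to two different terms is a load error, because
ambiguous strings inflate false positives in retrieval.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Iterable, Mapping

__all__ = [
    "DEFAULT_CATEGORIES",
    "LexiconEntry",
    "Lexicon",
    "LexiconError",
    "AmbiguousSynonymError",
    "load_lexicon",
    "save_lexicon",
    "lexicon_stats",
]

#: Default closed category vocabulary (12 labels).  Configurable at load time.
DEFAULT_CATEGORIES: tuple[str, ...] = (
    "pain type",
    "disorder",
    "drug",
    "drug class",
    "treatment",
    "surgical procedure",
    "anatomy",
    "condition",
    "molecule",
    "family",
    "gene",
    "physiology",
)

SPECIFICITY_WEIGHTS: Mapping[str, int] = {"specific": 2, "relevant": 1}


class LexiconError(ValueError):
    """Malformed lexicon input."""


class AmbiguousSynonymError(LexiconError):
    """The same synonym string is claimed by two entries."""


@dataclass(frozen=True)
class LexiconEntry:
    """One dictionary term with its case-sensitive synonyms.

    ``weight`` is derived from ``specificity`` (specific -> 2, relevant -> 1)
    and is the t_i factor used in document scoring.
    """

    term_id: str
    preferred_name: str
    synonyms: tuple[str, ...]
    category: str
    specificity: str

    def __post_init__(self) -> None:
        if self.specificity not in SPECIFICITY_WEIGHTS:
            raise LexiconError(
                f"term {self.term_id!r}: unknown specificity {self.specificity!r}"
            )
        if not self.synonyms:
            raise LexiconError(f"term {self.term_id!r}: no synonyms")
        if len(set(self.synonyms)) != len(self.synonyms):
            raise LexiconError(f"term {self.term_id!r}: duplicate synonyms within entry")
        if self.preferred_name not in self.synonyms:
            # preferred name always counts as a synonym of itself
            object.__setattr__(
                self, "synonyms", (self.preferred_name,) + tuple(self.synonyms)
            )

    @property
    def weight(self) -> int:
        return SPECIFICITY_WEIGHTS[self.specificity]


@dataclass
class Lexicon:
    """A validated set of entries plus an exact (case-sensitive) synonym index."""

    entries: list[LexiconEntry]
    categories: tuple[str, ...] = DEFAULT_CATEGORIES
    index: dict[str, LexiconEntry] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        index: dict[str, LexiconEntry] = {}
        for entry in self.entries:
            if entry.category not in self.categories:
                raise LexiconError(
                    f"term {entry.term_id!r}: category {entry.category!r} not in "
                    f"configured vocabulary"
                )
            for syn in entry.synonyms:
                prior = index.get(syn)
                if prior is not None and prior.term_id != entry.term_id:
                    raise AmbiguousSynonymError(
                        f"synonym {syn!r} claimed by entries "
                        f"{prior.term_id!r} and {entry.term_id!r}"
                    )
                index[syn] = entry
        self.index = index

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, term_id: str) -> LexiconEntry:
        for entry in self.entries:
            if entry.term_id == term_id:
                return entry
        raise KeyError(term_id)

    @property
    def by_term_id(self) -> dict[str, LexiconEntry]:
        return {e.term_id: e for e in self.entries}


_COLUMNS = ("term_id", "name", "category", "specificity", "synonyms")


def load_lexicon(
    path, categories: Iterable[str] = DEFAULT_CATEGORIES
) -> Lexicon:
    """Read a lexicon from TSV.

    Columns: term_id, name, category, specificity, synonyms (pipe-delimited,
    case-sensitive).  Unknown categories and cross-entry duplicate synonyms
    are rejected with an error naming the offending rows.
    """
    categories = tuple(categories)
    entries: list[LexiconEntry] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or tuple(reader.fieldnames) != _COLUMNS:
            raise LexiconError(
                f"{path}: expected header {list(_COLUMNS)}, got {reader.fieldnames}"
            )
        for lineno, row in enumerate(reader, start=2):
            category = row["category"]
            if category not in categories:
                raise LexiconError(
                    f"{path}:{lineno}: unknown category {category!r} "
                    f"(term {row['term_id']!r})"
                )
            synonyms = tuple(s for s in row["synonyms"].split("|") if s)
            entries.append(
                LexiconEntry(
                    term_id=row["term_id"],
                    preferred_name=row["name"],
                    synonyms=synonyms,
                    category=category,
                    specificity=row["specificity"],
                )
            )
    return Lexicon(entries, categories=categories)


def save_lexicon(lexicon: Lexicon, path) -> None:
    """Write a lexicon back to the TSV format read by :func:`load_lexicon`."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_COLUMNS)
        for e in lexicon.entries:
            writer.writerow(
                [e.term_id, e.preferred_name, e.category, e.specificity,
                 "|".join(e.synonyms)]
            )


def lexicon_stats(lexicon: Lexicon) -> dict[tuple[str, str], dict[str, int]]:
    """Per (category, specificity) counts of terms and synonyms.

    Returns a mapping ``(category, specificity) -> {"terms": n, "synonyms": m}``
    covering only populated cells; counts sum to the lexicon totals.
    """
    stats: dict[tuple[str, str], dict[str, int]] = {}
    for e in lexicon.entries:
        cell = stats.setdefault((e.category, e.specificity), {"terms": 0, "synonyms": 0})
        cell["terms"] += 1
        cell["synonyms"] += len(e.synonyms)
    return stats
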