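"""Corpus construction: dictionary matching, retrieval and document scoring.

Documents are sectioned literature records (title, abstract, MeSH descriptors,
optional full-text body paragraphs).  Lexicon terms are matched case-sensitively
at token boundaries with a leftmost-longest rule, the convention of
dictionary-based biomedical NER.  Retrieval keeps a document iff it mentions at
least one topic-*specific* term; the relevance score of a retained document then
uses every mention (specific and relevant):

    score = sum_i  t_i * p_i

where t_i is the term's specificity weight (2 specific / 1 relevant) and p_i a
section weight (title 2; abstract 1; MeSH 1; body 0.25).  Section weights are
configurable because full-text documents otherwise accumulate higher scores
than abstract-only records.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import Callable, Iterable, Iterator, Sequence

import numpy as np
from scipy import stats

from .lexicon import Lexicon, LexiconEntry

__all__ = [
    "Document",
    "TermMatch",
    "DocumentScore",
    "SECTION_WEIGHTS",
    "split_sentences",
    "tokenize",
    "match_terms",
    "score_document",
    "build_corpus",
    "stratified_sample",
    "compare_mesh_groups",
    "read_documents_jsonl",
    "write_documents_jsonl",
    "read_medline_xml",
]

SECTIONS = ("title", "abstract", "mesh", "body")

#: Default p_i by section; overridable in scoring calls.
SECTION_WEIGHTS: dict[str, float] = {
    "title": 2.0,
    "abstract": 1.0,
    "mesh": 1.0,
    "body": 0.25,
}


@dataclass(frozen=True)
class Document:
    """A sectioned literature record (abstract-only or full text)."""

    doc_id: str
    title: str
    abstract: str
    mesh: tuple[tuple[str, bool], ...] = ()  # (descriptor, is_major)
    body: tuple[str, ...] = ()  # paragraphs; empty for abstract-only records
    source: str = "medline"  # "medline" | "pmc"

    def section_texts(self) -> list[tuple[str, int, str]]:
        """Yield (section, paragraph_index, text) units to be matched."""
        units = [("title", 0, self.title), ("abstract", 0, self.abstract)]
        for i, (descriptor, _major) in enumerate(self.mesh):
            units.append(("mesh", i, descriptor))
        for i, para in enumerate(self.body):
            units.append(("body", i, para))
        return units


@dataclass(frozen=True)
class TermMatch:
    """One located occurrence of a lexicon synonym.

    ``char_span`` is a 0-based half-open span into the text of the matched
    unit (the title, the abstract, one MeSH descriptor or one body paragraph).
    """

    term_id: str
    matched_synonym: str
    section: str
    paragraph_index: int
    sentence_index: int
    char_span: tuple[int, int]


@dataclass
class DocumentScore:
    overall: float
    per_category: dict[str, float]
    per_term: dict[str, float]


_SENT_BOUNDARY = re.compile(r"[.!?]\s+(?=[A-Z0-9])")
_TOKEN = re.compile(r"\w+")


def split_sentences(text: str) -> list[tuple[int, int]]:
    """Half-open character spans of sentences under a simple boundary rule:
    a period/question/exclamation mark followed by whitespace and an
    uppercase letter or digit ends a sentence.  Pluggable by design; callers
    needing a smarter splitter can pass their own to :func:`match_terms`.
    """
    spans: list[tuple[int, int]] = []
    start = 0
    for m in _SENT_BOUNDARY.finditer(text):
        end = m.start() + 1  # include the punctuation mark
        spans.append((start, end))
        start = m.end()
    if start < len(text) or not spans:
        spans.append((start, len(text)))
    return spans


def tokenize(text: str) -> list[tuple[int, int]]:
    """Spans of word tokens (\\w+ runs)."""
    return [m.span() for m in _TOKEN.finditer(text)]


def _compile_matcher(synonyms: Iterable[str]) -> re.Pattern | None:
    # Longest alternatives first: at a given position the regex engine then
    # commits to the longest synonym, giving leftmost-longest semantics with
    # non-overlapping finditer scanning.
    ordered = sorted(set(synonyms), key=len, reverse=True)
    if not ordered:
        return None
    alternation = "|".join(re.escape(s) for s in ordered)
    return re.compile(rf"(?<![A-Za-z0-9])(?:{alternation})(?![A-Za-z0-9])")


_ABBREV = re.compile(r"\s*\(([A-Za-z0-9-]{1,10})\)")


def _sentence_index(spans: Sequence[tuple[int, int]], pos: int) -> int:
    for i, (s, e) in enumerate(spans):
        if s <= pos < max(e, s + 1):
            return i
    return len(spans) - 1


def match_terms(
    doc: Document,
    lexicon: Lexicon,
    *,
    capture_abbreviations: bool = False,
    sentence_splitter: Callable[[str], list[tuple[int, int]]] = split_sentences,
) -> list[TermMatch]:
    """Locate every lexicon synonym in the document.

    Case-sensitive, token-boundary anchored, leftmost-longest.  With
    ``capture_abbreviations`` a parenthetical immediately following a matched
    term (e.g. "complete Freund's adjuvant (CFA)") registers the abbreviation
    as a document-local synonym of the same entry and the document is
    re-scanned for it.
    """
    matcher = _compile_matcher(lexicon.index.keys())
    if matcher is None:
        return []

    units = doc.section_texts()
    matches: list[TermMatch] = []
    local_synonyms: dict[str, LexiconEntry] = {}

    def scan(pattern: re.Pattern, index: dict[str, LexiconEntry],
             skip_spans: dict[tuple[str, int], list[tuple[int, int]]] | None = None
             ) -> list[TermMatch]:
        out = []
        for section, para_idx, text in units:
            sent_spans = sentence_splitter(text)
            for m in pattern.finditer(text):
                if skip_spans:
                    taken = skip_spans.get((section, para_idx), [])
                    if any(s < m.end() and m.start() < e for s, e in taken):
                        continue
                entry = index[m.group(0)]
                out.append(
                    TermMatch(
                        term_id=entry.term_id,
                        matched_synonym=m.group(0),
                        section=section,
                        paragraph_index=para_idx,
                        sentence_index=_sentence_index(sent_spans, m.start()),
                        char_span=m.span(),
                    )
                )
                if capture_abbreviations:
                    trail = _ABBREV.match(text, m.end())
                    if trail:
                        abbr = trail.group(1)
                        if abbr not in lexicon.index and abbr not in local_synonyms:
                            local_synonyms[abbr] = entry
        return out

    matches = scan(matcher, lexicon.index)
    if capture_abbreviations and local_synonyms:
        taken: dict[tuple[str, int], list[tuple[int, int]]] = {}
        for tm in matches:
            taken.setdefault((tm.section, tm.paragraph_index), []).append(tm.char_span)
        abbr_matcher = _compile_matcher(local_synonyms.keys())
        if abbr_matcher is not None:
            matches.extend(scan(abbr_matcher, local_synonyms, skip_spans=taken))
    matches.sort(key=lambda t: (SECTIONS.index(t.section), t.paragraph_index,
                                t.char_span))
    return matches


def score_document(
    matches: Sequence[TermMatch],
    lexicon: Lexicon,
    section_weights: dict[str, float] | None = None,
) -> DocumentScore:
    """Sum t_i * p_i over every mention (repeated mentions each count)."""
    weights = SECTION_WEIGHTS if section_weights is None else section_weights
    by_id = lexicon.by_term_id
    per_term: dict[str, float] = {}
    per_category: dict[str, float] = {}
    overall = 0.0
    for tm in matches:
        entry = by_id.get(tm.term_id)
        if entry is None:
            raise KeyError(f"match references unknown term {tm.term_id!r}")
        contribution = entry.weight * weights[tm.section]
        overall += contribution
        per_term[tm.term_id] = per_term.get(tm.term_id, 0.0) + contribution
        per_category[entry.category] = (
            per_category.get(entry.category, 0.0) + contribution
        )
    return DocumentScore(overall=overall, per_category=per_category, per_term=per_term)


def build_corpus(
    docs: Iterable[Document],
    lexicon: Lexicon,
    *,
    section_weights: dict[str, float] | None = None,
    capture_abbreviations: bool = False,
) -> tuple[list[Document], dict[str, list[TermMatch]], dict[str, DocumentScore]]:
    """Retrieve the topic corpus from a document stream.

    A document is retained iff it has at least one match of a *specific*
    term; scores for retained documents use all matches (specific and
    relevant).  Duplicate doc_ids are an error.
    """
    by_id = lexicon.by_term_id
    seen: set[str] = set()
    retained: list[Document] = []
    all_matches: dict[str, list[TermMatch]] = {}
    scores: dict[str, DocumentScore] = {}
    for doc in docs:
        if doc.doc_id in seen:
            raise ValueError(f"duplicate doc_id {doc.doc_id!r}")
        seen.add(doc.doc_id)
        matches = match_terms(doc, lexicon,
                              capture_abbreviations=capture_abbreviations)
        if not any(by_id[tm.term_id].specificity == "specific" for tm in matches):
            continue
        retained.append(doc)
        all_matches[doc.doc_id] = matches
        scores[doc.doc_id] = score_document(matches, lexicon, section_weights)
    return retained, all_matches, scores


#: Score bands used for stratified evaluation sampling.
DEFAULT_BANDS: tuple[tuple[float, float], ...] = (
    (1.0, 3.0),
    (3.0, 10.0),
    (10.0, 25.0),
    (25.0, 50.0),
    (50.0, float("inf")),
)


def stratified_sample(
    scores: Sequence[tuple[str, float]],
    bands: Sequence[tuple[float, float]] = DEFAULT_BANDS,
    k: int = 10,
    seed: int = 0,
) -> dict[tuple[float, float], list[str]]:
    """Sample up to ``k`` doc_ids uniformly without replacement per score band.

    Bands are half-open ``[lo, hi)`` and must not overlap; a band with fewer
    than ``k`` members returns all members.  Reproducible per seed.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    ordered = sorted(bands)
    for (lo1, hi1), (lo2, _hi2) in zip(ordered, ordered[1:]):
        if lo2 < hi1:
            raise ValueError(f"overlapping bands ({lo1},{hi1}) and ({lo2},..)")
    rng = np.random.default_rng(seed)
    out: dict[tuple[float, float], list[str]] = {}
    for lo, hi in bands:
        members = sorted(doc_id for doc_id, s in scores if lo <= s < hi)
        if len(members) <= k:
            out[(lo, hi)] = members
        else:
            idx = rng.choice(len(members), size=k, replace=False)
            out[(lo, hi)] = [members[i] for i in sorted(idx)]
    return out


def compare_mesh_groups(
    scores_major: Sequence[float], scores_minor: Sequence[float]
) -> tuple[float, float]:
    """Rank-sum comparison of document scores between MeSH major/minor groups.

    Returns (Z, two-sided p).  Z is the tie-corrected normal approximation of
    the Mann-Whitney U statistic (negative when the first group ranks lower);
    the p-value uses the exact null distribution for small untied samples and
    the asymptotic one otherwise.
    """
    if len(scores_major) == 0 or len(scores_minor) == 0:
        raise ValueError("both score lists must be non-empty")
    x = np.asarray(scores_major, dtype=float)
    y = np.asarray(scores_minor, dtype=float)
    n1, n2 = len(x), len(y)
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    u = float(res.statistic)
    n = n1 + n2
    mu = n1 * n2 / 2.0
    pooled = np.concatenate([x, y])
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1))) if n > 1 else 0.0
    z = 0.0 if var <= 0 else (u - mu) / np.sqrt(var)
    p = 1.0 if var <= 0 else float(res.pvalue)
    return z, p


# ---------------------------------------------------------------------------
# I/O


def _doc_to_dict(doc: Document) -> dict:
    return {
        "id": doc.doc_id,
        "title": doc.title,
        "abstract": doc.abstract,
        "mesh": [{"descriptor": d, "major": m} for d, m in doc.mesh],
        "body": list(doc.body),
        "source": doc.source,
    }


def _doc_from_dict(d: dict) -> Document:
    return Document(
        doc_id=d["id"],
        title=d.get("title", ""),
        abstract=d.get("abstract", ""),
        mesh=tuple((m["descriptor"], bool(m.get("major", False)))
                   for m in d.get("mesh", [])),
        body=tuple(d.get("body", [])),
        source=d.get("source", "medline"),
    )


def read_documents_jsonl(path) -> Iterator[Document]:
    """Stream documents from a JSON Lines file (one record per line)."""
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                yield _doc_from_dict(json.loads(line))


def write_documents_jsonl(docs: Iterable[Document], path) -> int:
    n = 0
    with open(path, "w", encoding="utf-8") as fh:
        for doc in docs:
            fh.write(json.dumps(_doc_to_dict(doc)) + "\n")
            n += 1
    return n


def read_medline_xml(path) -> list[Document]:
    """Minimal Medline citation XML reader (PMID, ArticleTitle, AbstractText,
    MeshHeading/DescriptorName with MajorTopicYN)."""
    from lxml import etree

    tree = etree.parse(str(path))
    docs = []
    for citation in tree.iter("MedlineCitation"):
        pmid = citation.findtext("PMID", default="")
        title = citation.findtext(".//ArticleTitle", default="")
        abstract = " ".join(
            (el.text or "") for el in citation.findall(".//Abstract/AbstractText")
        ).strip()
        mesh = tuple(
            (dn.text or "", dn.get("MajorTopicYN", "N") == "Y")
            for dn in citation.findall(".//MeshHeading/DescriptorName")
        )
        docs.append(Document(doc_id=pmid, title=title, abstract=abstract,
                             mesh=mesh, source="medline"))
    return docs
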