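"""Term-to-event relevancy scoring.

Each (lexicon term, event-chain mention) pair in a document receives a score
on a 5-100 scale expressing how likely the term is to pertain to that event.
The score is tiered by textual configuration: a term in the same sentence as
the event scores 75-100 (closer to the trigger scores higher); the same
paragraph 60; a term in the title 55; in MeSH 50; in the abstract while the
event sits elsewhere 45; an adjacent body paragraph 30; and beyond that the
score decays with paragraph distance down to a floor of 5.  All tier values
live in :class:`RelevancyTiers` and can be overridden.

Per grouped event chain the link scores aggregate into an overall topic
relevancy: for each document d mentioning the group and each term t, take the
best link score s_td; terms with s_td > 50 contribute w_t * (s_td - 50) / 50
(w_t the term's specificity weight), and the sum is averaged over the group's
documents.  The disease variant is identical but unweighted and reported per
disease term.  Overall scores fall into bands: low (0), medium (>0, <=1),
high (>1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .corpus import Document, TermMatch, match_terms, split_sentences, tokenize
from .events import EventChainMention, GroupedEventChain
from .lexicon import Lexicon

__all__ = [
    "RelevancyTiers",
    "RelevancyLink",
    "OverallRelevancy",
    "term_event_relevancy",
    "overall_relevancy",
    "overall_disease_relevancy",
    "match_disease_terms",
    "band_for",
]


@dataclass(frozen=True)
class RelevancyTiers:
    """Tier values of the term-event relevancy score (all clamped to [5,100])."""

    same_sentence_base: float = 75.0
    same_sentence_span: float = 25.0
    same_paragraph: float = 60.0
    title: float = 55.0
    mesh: float = 50.0
    abstract: float = 45.0
    adjacent_body: float = 30.0   # body paragraphs one apart
    distant_base: float = 25.0    # decays 5 per extra paragraph of separation
    distant_step: float = 5.0
    default_gap: int = 2          # assumed separation when no paragraph distance applies
    floor: float = 5.0
    ceiling: float = 100.0


DEFAULT_TIERS = RelevancyTiers()


@dataclass(frozen=True)
class RelevancyLink:
    """A scored (term, event-chain mention) pair."""

    term_id: str
    doc_id: str
    mention_index: int
    score: float
    tier: str  # same_sentence | same_paragraph | title | mesh | abstract | same_section | distant

    def __post_init__(self) -> None:
        if not (5.0 <= self.score <= 100.0):
            raise ValueError(f"score {self.score} outside [5,100]")
        if self.tier == "same_sentence" and self.score < 75.0:
            raise ValueError("same-sentence links must score >= 75")


@dataclass
class OverallRelevancy:
    signature: str
    pain_score: float
    band: str
    disease_scores: dict[str, float] = field(default_factory=dict)


def band_for(score: float) -> str:
    if score == 0:
        return "low"
    return "medium" if score <= 1 else "high"


def _unit_text(doc: Document, section: str, paragraph_index: int) -> str:
    if section == "title":
        return doc.title
    if section == "abstract":
        return doc.abstract
    if section == "mesh":
        return doc.mesh[paragraph_index][0]
    return doc.body[paragraph_index]


def _token_index(spans: Sequence[tuple[int, int]], pos: int) -> int:
    for i, (s, e) in enumerate(spans):
        if pos < e:
            return i
    return max(len(spans) - 1, 0)


def term_event_relevancy(
    term_match: TermMatch,
    mention: EventChainMention,
    doc: Document,
    *,
    mention_index: int = 0,
    tiers: RelevancyTiers = DEFAULT_TIERS,
) -> RelevancyLink:
    """Score one (term match, event-chain mention) pair within a document."""
    if mention.doc_id != doc.doc_id:
        raise ValueError(
            f"mention belongs to {mention.doc_id!r}, not document {doc.doc_id!r}"
        )

    def clamp(x: float) -> float:
        return min(max(x, tiers.floor), tiers.ceiling)

    same_unit = (
        term_match.section == mention.section
        and term_match.paragraph_index == mention.paragraph_index
    )
    if same_unit and term_match.sentence_index == mention.sentence_index:
        # Proximity to the event trigger within the sentence drives the score.
        unit = _unit_text(doc, term_match.section, term_match.paragraph_index)
        sent_spans = split_sentences(unit)
        sent_start = sent_spans[min(term_match.sentence_index, len(sent_spans) - 1)][0]
        term_offset = term_match.char_span[0] - sent_start
        tokens = tokenize(mention.sentence_text)
        n_tokens = max(len(tokens), 1)
        i_term = _token_index(tokens, max(term_offset, 0))
        i_trig = _token_index(tokens, mention.root.trigger_span[0])
        d = abs(i_term - i_trig)
        score = tiers.same_sentence_base + round(
            tiers.same_sentence_span * (1 - d / max(n_tokens - 1, 1))
        )
        return RelevancyLink(term_match.term_id, doc.doc_id, mention_index,
                             clamp(score), "same_sentence")
    if same_unit:
        return RelevancyLink(term_match.term_id, doc.doc_id, mention_index,
                             clamp(tiers.same_paragraph), "same_paragraph")
    if term_match.section == "title":
        return RelevancyLink(term_match.term_id, doc.doc_id, mention_index,
                             clamp(tiers.title), "title")
    if term_match.section == "mesh":
        return RelevancyLink(term_match.term_id, doc.doc_id, mention_index,
                             clamp(tiers.mesh), "mesh")
    if term_match.section == "abstract":
        return RelevancyLink(term_match.term_id, doc.doc_id, mention_index,
                             clamp(tiers.abstract), "abstract")
    if term_match.section == "body" and mention.section == "body":
        gap = abs(term_match.paragraph_index - mention.paragraph_index)
        if gap == 1:
            return RelevancyLink(term_match.term_id, doc.doc_id, mention_index,
                                 clamp(tiers.adjacent_body), "same_section")
    else:
        gap = tiers.default_gap
    score = max(tiers.floor, tiers.distant_base - tiers.distant_step * (gap - 1))
    return RelevancyLink(term_match.term_id, doc.doc_id, mention_index,
                         clamp(score), "distant")


def _per_term_contributions(
    group: GroupedEventChain, links: Sequence[RelevancyLink]
) -> tuple[set[str], dict[str, dict[str, float]]]:
    """Best link score per (term, document): returns (docs, term -> doc -> s_td)."""
    docs = {m.doc_id for m in group.mentions}
    best: dict[str, dict[str, float]] = {}
    for link in links:
        if link.doc_id not in docs:
            raise ValueError(
                f"link for doc {link.doc_id!r} does not belong to group {group.signature!r}"
            )
        per_doc = best.setdefault(link.term_id, {})
        per_doc[link.doc_id] = max(per_doc.get(link.doc_id, 0.0), link.score)
    return docs, best


def overall_relevancy(
    group: GroupedEventChain,
    links: Sequence[RelevancyLink],
    lexicon: Lexicon,
    *,
    cutoff: float = 50.0,
) -> OverallRelevancy:
    """Aggregate link scores into the group's overall topic relevancy.

    overall = (1/|D|) * sum_d sum_{t: s_td > cutoff} w_t * (s_td - cutoff) / cutoff
    where D is the set of documents mentioning the group and w_t the term's
    specificity weight.
    """
    docs, best = _per_term_contributions(group, links)
    by_id = lexicon.by_term_id
    total = 0.0
    for term_id, per_doc in best.items():
        w = by_id[term_id].weight
        for s in per_doc.values():
            if s > cutoff:
                total += w * (s - cutoff) / cutoff
    score = total / len(docs) if docs else 0.0
    return OverallRelevancy(signature=group.signature, pain_score=score,
                            band=band_for(score))


def overall_disease_relevancy(
    group: GroupedEventChain,
    links: Sequence[RelevancyLink],
    *,
    cutoff: float = 50.0,
) -> dict[str, float]:
    """Per-disease-term overall relevancy (unweighted variant)."""
    docs, best = _per_term_contributions(group, links)
    out: dict[str, float] = {}
    for term_id, per_doc in best.items():
        total = sum((s - cutoff) / cutoff for s in per_doc.values() if s > cutoff)
        out[term_id] = total / len(docs) if docs else 0.0
    return out


def match_disease_terms(doc: Document, disease_lexicon: Lexicon) -> list[TermMatch]:
    """Locate disease-lexicon terms in a document (same matcher as the topic
    lexicon; disease terms conventionally all carry weight 1)."""
    return match_terms(doc, disease_lexicon)
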