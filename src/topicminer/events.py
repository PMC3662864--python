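"""Event chains: per-mention molecular events and their grouping.

An event chain is a nested molecular event extracted from a single sentence:
one to three linked events over the nine GENIA-style event types.  Metabolic
events (gene expression, transcription, protein catabolism), phosphorylation
and localization take one molecule as theme; binding takes one or more; the
three regulation types may take another event as theme and may carry a cause.

Mentions of the same chain across sentences and documents are grouped under a
canonical signature.  Identity uses Entrez Gene IDs where participants are
normalized (never gene symbols, which are ambiguous) and lowercased surface
text otherwise.  Binding is symmetric, so binding themes are sorted —
numerically by Entrez ID when all are normalized, case-insensitively
alphabetically otherwise — before serialization.  Regulation cause/theme
asymmetry is preserved: swapping them yields a different chain.

A group records total mention frequency, the number of distinct documents,
the maximum extractor confidence over its mentions, and aggregated negation
and speculation status.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence, Union

__all__ = [
    "EVENT_TYPES",
    "REGULATION_TYPES",
    "Participant",
    "EventNode",
    "EventChainMention",
    "GroupedEventChain",
    "canonical_signature",
    "group_event_chains",
    "classify_polarity",
    "annotate_go",
    "summarize_context",
    "iter_participants",
    "iter_event_nodes",
    "load_event_mentions",
    "write_groups_tsv",
    "write_groups_json",
]

EVENT_TYPES = frozenset(
    {
        "gene_expression",
        "transcription",
        "protein_catabolism",
        "phosphorylation",
        "localization",
        "binding",
        "regulation",
        "positive_regulation",
        "negative_regulation",
    }
)
REGULATION_TYPES = frozenset({"regulation", "positive_regulation", "negative_regulation"})

MAX_CHAIN_EVENTS = 3


@dataclass
class Participant:
    """A gene/protein/RNA mention, optionally normalized.

    Normalization chain: species (taxid), then Entrez Gene ID, then homologene
    ID.  ``go_terms`` and ``mutations`` are filled by downstream annotators.
    """

    mention_text: str
    char_span: tuple[int, int] = (0, 0)
    entrez_id: int | None = None
    species_taxid: int | None = None
    homologene_id: int | None = None
    go_terms: set[str] = field(default_factory=set)
    mutations: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.entrez_id is not None and self.entrez_id <= 0:
            raise ValueError(f"entrez_id must be positive, got {self.entrez_id}")

    @property
    def normalized(self) -> bool:
        return self.entrez_id is not None

    def identity_key(self) -> str:
        """Grouping identity: Entrez ID when normalized, else surface text."""
        if self.entrez_id is not None:
            return f"G:{self.entrez_id}"
        return f"U:{self.mention_text.lower()}"


Argument = Union[Participant, "EventNode"]


@dataclass
class EventNode:
    event_type: str
    themes: list[Argument]
    cause: Argument | None = None
    trigger_text: str = ""
    trigger_span: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise ValueError(f"unknown event type {self.event_type!r}")
        if not self.themes:
            raise ValueError(f"{self.event_type}: at least one theme required")
        if len(self.themes) > 1 and self.event_type != "binding":
            raise ValueError(f"{self.event_type}: only binding may have >1 theme")
        if self.event_type not in REGULATION_TYPES:
            if self.cause is not None:
                raise ValueError(f"{self.event_type}: only regulation events take a cause")
            if any(isinstance(t, EventNode) for t in self.themes):
                raise ValueError(
                    f"{self.event_type}: only regulation events may take an event theme"
                )

    def n_events(self) -> int:
        n = 1
        for arg in list(self.themes) + ([self.cause] if self.cause else []):
            if isinstance(arg, EventNode):
                n += arg.n_events()
        return n


@dataclass
class EventChainMention:
    """One textual mention of an event chain in one sentence."""

    doc_id: str
    sentence_text: str
    section: str
    paragraph_index: int
    sentence_index: int
    root: EventNode
    confidence: float
    negated: bool = False
    speculated: bool = False
    anatomy_terms: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not (0.0 <= self.confidence <= 1.0):
            raise ValueError(f"confidence must be in [0,1], got {self.confidence}")
        if self.root.n_events() > MAX_CHAIN_EVENTS:
            raise ValueError(
                f"event chain has {self.root.n_events()} events (max {MAX_CHAIN_EVENTS})"
            )


@dataclass
class GroupedEventChain:
    """The deduplicated record of all mentions sharing one signature."""

    signature: str
    mentions: list[EventChainMention]

    @property
    def frequency(self) -> int:
        return len(self.mentions)

    @property
    def doc_count(self) -> int:
        return len({m.doc_id for m in self.mentions})

    @property
    def confidence(self) -> float:
        return max(m.confidence for m in self.mentions)

    @property
    def participant_count(self) -> int:
        """Number of molecule slots in the chain (a homodimer binding counts 2)."""
        return sum(1 for _ in iter_participants(self.mentions[0].root))

    @property
    def chain_class(self) -> str:
        n = self.participant_count
        if n == 1:
            return "single_event"
        if n == 2:
            return "molecular_interaction"
        return "multi"

    @property
    def is_self_interaction(self) -> bool:
        keys = [p.identity_key() for p in iter_participants(self.mentions[0].root)]
        return len(keys) == 2 and keys[0] == keys[1]

    @property
    def polarity(self) -> str:
        return classify_polarity(self)[0]

    @property
    def speculation(self) -> str:
        return classify_polarity(self)[1]


def iter_participants(node: EventNode) -> Iterable[Participant]:
    """Participants of a chain in tree order (themes, then cause)."""
    for arg in node.themes:
        if isinstance(arg, EventNode):
            yield from iter_participants(arg)
        else:
            yield arg
    if node.cause is not None:
        if isinstance(node.cause, EventNode):
            yield from iter_participants(node.cause)
        else:
            yield node.cause


def iter_event_nodes(node: EventNode) -> Iterable[EventNode]:
    yield node
    for arg in list(node.themes) + ([node.cause] if node.cause else []):
        if isinstance(arg, EventNode):
            yield from iter_event_nodes(arg)


def _participant_sig(p: Participant) -> str:
    return p.identity_key()


def _binding_sort_key(arg: Participant) -> tuple:
    # Normalized participants first, numerically by Entrez ID; unnormalized
    # after, case-insensitively alphabetical by surface text.
    if arg.entrez_id is not None:
        return (0, arg.entrez_id, "")
    return (1, 0, arg.mention_text.lower())


def _node_sig(node: EventNode) -> str:
    themes = node.themes
    if node.event_type == "binding":
        themes = sorted(themes, key=_binding_sort_key)  # type: ignore[arg-type]
    parts = []
    for t in themes:
        parts.append(_node_sig(t) if isinstance(t, EventNode) else _participant_sig(t))
    sig = f"{node.event_type}({','.join(parts)}"
    if node.cause is not None:
        cause = (_node_sig(node.cause) if isinstance(node.cause, EventNode)
                 else _participant_sig(node.cause))
        sig += f";cause={cause}"
    return sig + ")"


def canonical_signature(mention: EventChainMention) -> str:
    """Stable grouping key for a mention: prefix-notation serialization of the
    event tree with binding themes in canonical order and participants
    identified by Entrez ID (or lowercased text when unnormalized).

    The format is a stable external contract — signatures serve as join keys
    across pipeline stages and releases.
    """
    return _node_sig(mention.root)


def group_event_chains(
    mentions: Iterable[EventChainMention],
) -> list[GroupedEventChain]:
    """Group mentions by canonical signature.

    Output is deterministic: descending frequency, then signature.
    """
    buckets: dict[str, list[EventChainMention]] = {}
    for m in mentions:
        buckets.setdefault(canonical_signature(m), []).append(m)
    groups = [GroupedEventChain(signature=sig, mentions=ms) for sig, ms in buckets.items()]
    groups.sort(key=lambda g: (-g.frequency, g.signature))
    return groups


def classify_polarity(group: GroupedEventChain) -> tuple[str, str]:
    """Aggregate negation / speculation status over a group's mentions.

    Polarity: all_negative iff every mention is negated, all_positive iff
    none is, mixed otherwise (a potential literature contradiction).
    Speculation: none / all / mixed analogously.
    """
    if not group.mentions:
        raise ValueError("empty group")
    neg = [m.negated for m in group.mentions]
    spec = [m.speculated for m in group.mentions]
    if all(neg):
        polarity = "all_negative"
    elif any(neg):
        polarity = "mixed"
    else:
        polarity = "all_positive"
    if all(spec):
        speculation = "all"
    elif any(spec):
        speculation = "mixed"
    else:
        speculation = "none"
    return polarity, speculation


def annotate_go(
    groups: Sequence[GroupedEventChain],
    gene2go: Iterable[tuple[int, str]] | Mapping[int, Iterable[str]],
    goslim: Mapping[str, str] | None = None,
) -> None:
    """Fill participant ``go_terms`` from a gene2go-style mapping (in place).

    Each normalized participant receives the union of its mapped GO IDs and,
    when a GO->slim mapping is supplied, their slim IDs.  Unnormalized
    participants are left untouched.
    """
    if isinstance(gene2go, Mapping):
        table = {int(k): set(v) for k, v in gene2go.items()}
    else:
        table = {}
        for entrez, go_id in gene2go:
            table.setdefault(int(entrez), set()).add(go_id)
    goslim = goslim or {}
    for group in groups:
        for mention in group.mentions:
            for p in iter_participants(mention.root):
                if p.entrez_id is None:
                    continue
                gos = table.get(p.entrez_id, set())
                p.go_terms |= gos
                p.go_terms |= {goslim[g] for g in gos if g in goslim}


def summarize_context(groups: Sequence[GroupedEventChain]) -> dict:
    """Frequency tables over groups.

    ``anatomy``: anatomy term -> mention count (over all mentions).
    ``event_types``: event type -> per-class counts where ``non_redundant``
    counts each group once per event type present in its chain and ``total``
    counts repeated occurrences within the chain (regulation of regulation
    counts twice in total).
    """
    anatomy: Counter[str] = Counter()
    event_types: dict[str, dict[str, dict[str, int]]] = {}
    for group in groups:
        for m in group.mentions:
            anatomy.update(m.anatomy_terms)
        type_counts = Counter(n.event_type for n in iter_event_nodes(group.mentions[0].root))
        cls = group.chain_class
        for etype, total in type_counts.items():
            per_class = event_types.setdefault(etype, {})
            for key in (cls, "all"):
                cell = per_class.setdefault(key, {"non_redundant": 0, "total": 0})
                cell["non_redundant"] += 1
                cell["total"] += total
    return {"anatomy": dict(anatomy), "event_types": event_types}


# ---------------------------------------------------------------------------
# JSON / TSV serialization (flattened event-chain export schema)


def _participant_from_dict(d: dict) -> Participant:
    return Participant(
        mention_text=d["text"],
        char_span=tuple(d.get("span", (0, 0))),
        entrez_id=d.get("entrez_id"),
        species_taxid=d.get("species_taxid"),
        homologene_id=d.get("homologene_id"),
    )


def _node_from_dict(d: dict) -> EventNode:
    def arg(a: dict) -> Argument:
        return _node_from_dict(a) if "event_type" in a else _participant_from_dict(a)

    trigger = d.get("trigger", {})
    return EventNode(
        event_type=d["event_type"],
        themes=[arg(t) for t in d["themes"]],
        cause=arg(d["cause"]) if d.get("cause") else None,
        trigger_text=trigger.get("text", ""),
        trigger_span=tuple(trigger.get("span", (0, 0))),
    )


def _participant_to_dict(p: Participant) -> dict:
    d: dict = {"text": p.mention_text, "span": list(p.char_span)}
    for k in ("entrez_id", "species_taxid", "homologene_id"):
        v = getattr(p, k)
        if v is not None:
            d[k] = v
    return d


def _node_to_dict(n: EventNode) -> dict:
    def arg(a: Argument) -> dict:
        return _node_to_dict(a) if isinstance(a, EventNode) else _participant_to_dict(a)

    d: dict = {
        "event_type": n.event_type,
        "trigger": {"text": n.trigger_text, "span": list(n.trigger_span)},
        "themes": [arg(t) for t in n.themes],
    }
    if n.cause is not None:
        d["cause"] = arg(n.cause)
    return d


def mention_to_dict(m: EventChainMention) -> dict:
    return {
        "doc_id": m.doc_id,
        "sentence_text": m.sentence_text,
        "section": m.section,
        "paragraph_index": m.paragraph_index,
        "sentence_index": m.sentence_index,
        "confidence": m.confidence,
        "negated": m.negated,
        "speculated": m.speculated,
        "anatomy_terms": list(m.anatomy_terms),
        "root": _node_to_dict(m.root),
    }


def mention_from_dict(d: dict) -> EventChainMention:
    return EventChainMention(
        doc_id=d["doc_id"],
        sentence_text=d["sentence_text"],
        section=d.get("section", "abstract"),
        paragraph_index=d.get("paragraph_index", 0),
        sentence_index=d.get("sentence_index", 0),
        root=_node_from_dict(d["root"]),
        confidence=d["confidence"],
        negated=d.get("negated", False),
        speculated=d.get("speculated", False),
        anatomy_terms=tuple(d.get("anatomy_terms", ())),
    )


def load_event_mentions(path) -> list[EventChainMention]:
    """Load per-mention event chains from the JSON export schema."""
    with open(path, encoding="utf-8") as fh:
        data = json.load(fh)
    return [mention_from_dict(d) for d in data]


def save_event_mentions(mentions: Sequence[EventChainMention], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump([mention_to_dict(m) for m in mentions], fh, indent=1)


def write_groups_tsv(groups: Sequence[GroupedEventChain], path) -> None:
    import csv

    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ["signature", "class", "frequency", "doc_count", "confidence",
             "polarity", "speculation", "self_interaction"]
        )
        for g in groups:
            pol, spec = classify_polarity(g)
            writer.writerow(
                [g.signature, g.chain_class, g.frequency, g.doc_count,
                 f"{g.confidence:.6g}", pol, spec, int(g.is_self_interaction)]
            )


def write_groups_json(groups: Sequence[GroupedEventChain], path) -> None:
    payload = []
    for g in groups:
        pol, spec = classify_polarity(g)
        payload.append(
            {
                "signature": g.signature,
                "class": g.chain_class,
                "frequency": g.frequency,
                "doc_count": g.doc_count,
                "confidence": g.confidence,
                "polarity": pol,
                "speculation": spec,
                "self_interaction": g.is_self_interaction,
                "mentions": [mention_to_dict(m) for m in g.mentions],
            }
        )
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1)
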