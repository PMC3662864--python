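"""Point-mutation detection and mutation-to-protein linking.

Detection normalizes substitution mentions to the wNm form (wild-type residue,
position, mutant residue): one-letter "A123T", three-letter "Ala123Thr", and
verbose "A123 to T" / "Ala123 to Thr" styles.  One-letter matches require a
two-digit position — single-digit forms collide with gene, histone and
cell-marker names (H2A, S100B) far too often for a precision-oriented linker.

Linking associates each detected mutation with at most one protein mention in
the same sentence by trying a priority-ranked list of textual patterns
(lowest pattern id wins).  Enumerated mutation lists ("mutations A30P, E46K
and A53T for SNCA") distribute over their single trailing protein.  The
contract is precision-oriented: a link is emitted only when a pattern fires;
mutations that no pattern covers are reported unlinked.  Cross-sentence
anaphora is out of scope.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Sequence

from .events import Participant

__all__ = [
    "AA3_TO_1",
    "MutationMention",
    "MutationLink",
    "LinkPattern",
    "DEFAULT_PATTERNS",
    "find_mutations",
    "link_mutations",
    "load_patterns",
]

#: Three-letter to one-letter amino-acid codes.
AA3_TO_1: dict[str, str] = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C",
    "Gln": "Q", "Glu": "E", "Gly": "G", "His": "H", "Ile": "I",
    "Leu": "L", "Lys": "K", "Met": "M", "Phe": "F", "Pro": "P",
    "Ser": "S", "Thr": "T", "Trp": "W", "Tyr": "Y", "Val": "V",
}
AA1 = frozenset(AA3_TO_1.values())

_AA3 = "|".join(AA3_TO_1)
# Order matters: verbose and three-letter forms before the bare one-letter form.
_MUTATION_RE = re.compile(
    rf"""
    (?<![A-Za-z0-9])
    (?:
        (?P<w3v>{_AA3})(?P<pos3v>\d+)\s+to\s+(?P<m3v>{_AA3})(?![a-z])   # Ala123 to Thr
      | (?P<w1v>[A-Z])(?P<pos1v>\d+)\s+to\s+(?P<m1v>[A-Z])(?![A-Za-z0-9]) # A123 to T
      | (?P<w3>{_AA3})(?P<pos3>\d+)(?P<m3>{_AA3})(?![A-Za-z0-9])        # Ala123Thr
      | (?P<w1>[A-Z])(?P<pos1>\d\d+)(?P<m1>[A-Z])(?![A-Za-z0-9])        # A123T
    )
    """,
    re.VERBOSE,
)


@dataclass(frozen=True)
class MutationMention:
    raw_text: str
    normalized: str  # wNm, one-letter codes
    char_span: tuple[int, int]

    def __post_init__(self) -> None:
        wt, mut = self.normalized[0], self.normalized[-1]
        pos = int(self.normalized[1:-1])
        if wt not in AA1 or mut not in AA1:
            raise ValueError(f"invalid residue code in {self.normalized!r}")
        if pos < 1:
            raise ValueError(f"position must be >= 1 in {self.normalized!r}")


@dataclass(frozen=True)
class MutationLink:
    protein: Participant
    mutation: MutationMention
    pattern_id: int


def find_mutations(sentence: str) -> list[MutationMention]:
    """Detect and normalize point-mutation mentions in one sentence."""
    out: list[MutationMention] = []
    for m in _MUTATION_RE.finditer(sentence):
        gd = m.groupdict()
        if gd["w3v"]:
            wt, pos, mut = AA3_TO_1[gd["w3v"]], gd["pos3v"], AA3_TO_1[gd["m3v"]]
        elif gd["w1v"]:
            wt, pos, mut = gd["w1v"], gd["pos1v"], gd["m1v"]
        elif gd["w3"]:
            wt, pos, mut = AA3_TO_1[gd["w3"]], gd["pos3"], AA3_TO_1[gd["m3"]]
        else:
            wt, pos, mut = gd["w1"], gd["pos1"], gd["m1"]
        if wt not in AA1 or mut not in AA1:
            continue
        out.append(
            MutationMention(
                raw_text=m.group(0),
                normalized=f"{wt}{int(pos)}{mut}",
                char_span=m.span(),
            )
        )
    return out


@dataclass(frozen=True)
class LinkPattern:
    """One linking rule: a regex over the gap text between the two mentions.

    ``order`` is "protein_first" (pattern matches the text from the protein's
    end to the mutation's start) or "mutation_first" (mutation end to protein
    start).  ``enumeration`` marks rules where several mutations share the
    trailing protein, the gap being checked from the *last* mutation.
    Patterns are data: they can be replaced wholesale from a pattern file.
    """

    pattern_id: int
    order: str
    gap_regex: str
    enumeration: bool = False
    enabled: bool = True


#: Default priority-ranked rules (lowest id tried first).
DEFAULT_PATTERNS: tuple[LinkPattern, ...] = (
    # "<protein> - <mutation>", "<protein>: <mutation>", "<protein> (<mutation>"
    LinkPattern(1, "protein_first", r"\s*[-–—:(]\s*"),
    # "<mutation> of|in <protein>", e.g. "the A53T mutation in SNCA"
    LinkPattern(2, "mutation_first",
                r"\s*(?:mutation|substitution|variant)?s?\s*(?:of|in)\s+(?:the\s+)?",
                enumeration=True),
    # "<mutation> for the <protein>"
    LinkPattern(3, "mutation_first",
                r"\s*(?:mutation|substitution|variant)?s?\s*for\s+(?:the\s+)?",
                enumeration=True),
    # "mutations <A>, <B> and <C> for|of|in <protein>"
    LinkPattern(4, "mutation_first", r"\s*(?:for|of|in)\s+(?:the\s+)?", enumeration=True),
    # nearest protein within 5 tokens; recall-oriented fallback, off by default
    LinkPattern(5, "either", r"", enabled=False),
)

_TOKEN = re.compile(r"\S+")


def load_patterns(path) -> list[LinkPattern]:
    """Read linking rules from a TSV file: id, order, enumeration(0/1), regex."""
    patterns = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            pid, order, enum_flag, regex = line.split("\t", 3)
            patterns.append(
                LinkPattern(int(pid), order, regex, enumeration=bool(int(enum_flag)))
            )
    return sorted(patterns, key=lambda p: p.pattern_id)


def _gap(sentence: str, left_end: int, right_start: int) -> str | None:
    if left_end > right_start:
        return None
    return sentence[left_end:right_start]


def _enumeration_block(
    sentence: str, mutations: Sequence[MutationMention], last: MutationMention
) -> list[MutationMention]:
    """Mutations forming a comma/and-separated run ending at ``last``."""
    ordered = sorted(mutations, key=lambda m: m.char_span)
    idx = ordered.index(last)
    block = [last]
    for prev in reversed(ordered[:idx]):
        gap = sentence[prev.char_span[1] : block[0].char_span[0]]
        if re.fullmatch(r"\s*(?:,\s*(?:and|or)?|and|or)\s*", gap):
            block.insert(0, prev)
        else:
            break
    return block


def link_mutations(
    sentence: str,
    protein_mentions: Sequence[Participant],
    mutations: Sequence[MutationMention],
    patterns: Sequence[LinkPattern] = DEFAULT_PATTERNS,
    *,
    enable_fallback: bool = False,
) -> tuple[list[MutationLink], list[MutationMention]]:
    """Link each mutation to at most one protein mention in the sentence.

    Rules are tried in priority order (ascending pattern_id); the first rule
    that fires for a mutation wins.  Returns (links, unlinked mutations).
    """
    links: list[MutationLink] = []
    linked: set[tuple[int, int]] = set()

    for pat in sorted(patterns, key=lambda p: p.pattern_id):
        if not pat.enabled and not (pat.pattern_id == 5 and enable_fallback):
            continue
        for mut in mutations:
            if mut.char_span in linked:
                continue
            if pat.pattern_id == 5:
                best = _nearest_protein(sentence, protein_mentions, mut)
                if best is not None:
                    links.append(MutationLink(best, mut, pat.pattern_id))
                    linked.add(mut.char_span)
                continue
            for prot in protein_mentions:
                if pat.order == "protein_first":
                    gap = _gap(sentence, prot.char_span[1], mut.char_span[0])
                else:
                    gap = _gap(sentence, mut.char_span[1], prot.char_span[0])
                if gap is None or not re.fullmatch(pat.gap_regex, gap):
                    continue
                if pat.enumeration:
                    block = _enumeration_block(sentence, mutations, mut)
                else:
                    block = [mut]
                for member in block:
                    if member.char_span not in linked:
                        links.append(MutationLink(prot, member, pat.pattern_id))
                        linked.add(member.char_span)
                break

    unlinked = [m for m in mutations if m.char_span not in linked]
    links.sort(key=lambda l: l.mutation.char_span)
    return links, unlinked


def _nearest_protein(
    sentence: str, proteins: Sequence[Participant], mut: MutationMention,
    max_tokens: int = 5,
) -> Participant | None:
    best: tuple[int, Participant] | None = None
    for prot in proteins:
        if prot.char_span[1] <= mut.char_span[0]:
            between = sentence[prot.char_span[1] : mut.char_span[0]]
        elif mut.char_span[1] <= prot.char_span[0]:
            between = sentence[mut.char_span[1] : prot.char_span[0]]
        else:
            continue
        dist = len(_TOKEN.findall(between))
        if dist <= max_tokens and (best is None or dist < best[0]):
            best = (dist, prot)
    return best[1] if best else None
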