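"""Synthetic fixture bundles with controlled, fully recorded ground truth.

The generator emulates the inputs of the pipeline — sectioned literature
records, a weighted topic lexicon, a disease lexicon, per-sentence event-chain
annotations with normalization/negation/speculation/anatomy context, a gold
gene set, a gene2go table and curation labels — without any external data.
Sentences are template-generated token strings: linguistic realism is out of
scope; what downstream code consumes is structural realism (sections, char
offsets, event nesting, flags, confidence mixtures).

Every planted fact (term mention offsets, unique chain signatures with
frequencies and document counts, mutation-protein associations) is recorded
in a manifest, and :func:`manifest_check` re-runs the pipeline against it.
Generation is fully deterministic per seed.

Token pools are constructed pairwise disjoint (lexicon terms, disease terms,
filler vocabulary, gene surface forms, anatomy terms, template scaffolding)
so that planted counts are exact: a term can only match where it was placed.

Extractor confidence emulates a text-mining confidence score: mentions of
true interactions draw from a beta distribution with mean 0.30 and mentions
of false ones from mean 0.10, the separation the triage model is meant to
exploit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .corpus import Document, build_corpus, match_terms
from .curation_stats import CurationRecord
from .events import (
    EventChainMention,
    EventNode,
    Participant,
    canonical_signature,
    group_event_chains,
    save_event_mentions,
)
from .lexicon import Lexicon, LexiconEntry, save_lexicon
from .mutation_link import find_mutations, link_mutations

__all__ = ["SimConfig", "Bundle", "generate", "generate_pair", "write_bundle",
           "manifest_check"]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic bundle.

    Planted-term rates are fractions of documents receiving one planted
    mention in that section (placed exactly, not sampled-then-lost).
    Confidence means follow the separation reported for curated text-mined
    interactions: true 0.30, false 0.10.
    """

    n_docs: int = 300
    fulltext_fraction: float = 0.3
    seed: int = 0

    # planted topic-term mention rates per section, by specificity
    title_specific_rate: float = 0.15
    abstract_specific_rate: float = 0.5
    mesh_specific_rate: float = 0.3
    body_specific_rate: float = 0.2
    title_relevant_rate: float = 0.05
    abstract_relevant_rate: float = 0.4
    mesh_relevant_rate: float = 0.2
    body_relevant_rate: float = 0.2
    disease_rate: float = 0.3

    # event generation
    events_per_doc_mean: float = 3.0
    events_per_doc_max: int = 8
    max_sentences_per_doc: int = 20
    new_chain_prob: float = 0.45      # chance a mention starts a new unique chain
    binding_fraction: float = 0.35
    regulation_fraction: float = 0.35  # remainder are single events
    deep_chain_fraction: float = 0.1   # 3-event chains among regulations
    unnormalized_rate: float = 0.15
    negation_rate: float = 0.10
    speculation_rate: float = 0.05
    mutation_rate: float = 0.10
    mutation_patternless_rate: float = 0.0

    # gene pool and gold-set enrichment
    n_genes: int = 60
    n_gold_genes: int = 12
    gold_seed: int = 7  # gold-set draw; shared across a focus/background pair
    gold_baseline_prob: float = 0.15   # background P(chain mentions a gold gene)
    gold_enrichment_factor: float = 2.0

    # curated-truth mixture
    tp_fraction: float = 0.4
    confidence_mean_true: float = 0.30
    confidence_mean_false: float = 0.10

    def __post_init__(self) -> None:
        rates = [
            self.fulltext_fraction, self.title_specific_rate,
            self.abstract_specific_rate, self.mesh_specific_rate,
            self.body_specific_rate, self.title_relevant_rate,
            self.abstract_relevant_rate, self.mesh_relevant_rate,
            self.body_relevant_rate, self.disease_rate, self.new_chain_prob,
            self.binding_fraction, self.regulation_fraction,
            self.deep_chain_fraction, self.unnormalized_rate,
            self.negation_rate, self.speculation_rate, self.mutation_rate,
            self.mutation_patternless_rate, self.gold_baseline_prob,
            self.tp_fraction,
        ]
        if any(not (0.0 <= r <= 1.0) for r in rates):
            raise ValueError("all rates must be in [0,1]")
        if self.events_per_doc_max > self.max_sentences_per_doc:
            raise ValueError(
                "events per document exceed the sentence capacity of a document"
            )
        if self.n_gold_genes > self.n_genes:
            raise ValueError("gold set larger than gene pool")
        if self.gold_enrichment_factor <= 0:
            raise ValueError("enrichment factor must be positive")


@dataclass
class Bundle:
    config: SimConfig
    documents: list[Document]
    lexicon: Lexicon
    disease_lexicon: Lexicon
    mentions: list[EventChainMention]
    gold_genes: set[int]
    gene2go: list[tuple[int, str]]
    curation: list[CurationRecord]
    manifest: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# fixed vocabulary pools (pairwise token-disjoint by construction)

_SPECIFIC_TERMS = [
    # (term_id, name, category, synonyms)
    ("P001", "neuropathic pain", "pain type", ["neuropathic pain"]),
    ("P002", "allodynia", "condition", ["allodynia", "mechanical allodynia"]),
    ("P003", "hyperalgesia", "condition", ["hyperalgesia", "thermal hyperalgesia"]),
    ("P004", "analgesia", "pain type", ["analgesia"]),
    ("P005", "morphine", "drug", ["morphine"]),
    ("P006", "fibromyalgia", "disorder", ["fibromyalgia"]),
    ("P007", "sciatica", "disorder", ["sciatica"]),
    ("P008", "migraine", "disorder", ["migraine", "hemicrania"]),
    ("P009", "opioid analgesic", "drug class", ["opioid analgesic", "opioid analgesics"]),
    ("P010", "rhizotomy", "surgical procedure", ["rhizotomy"]),
]
_RELEVANT_TERMS = [
    ("R001", "dorsal root ganglion", "anatomy", ["dorsal root ganglion"]),
    ("R002", "locus caeruleus", "anatomy", ["locus caeruleus"]),
    ("R003", "nociceptor", "physiology", ["nociceptor", "nociceptors"]),
    ("R004", "spinal cord", "anatomy", ["spinal cord"]),
    ("R005", "opioid receptor", "gene", ["opioid receptor"]),
    ("R006", "capsaicin", "molecule", ["capsaicin"]),
    ("R007", "bradykinin", "molecule", ["bradykinin"]),
    ("R008", "prostaglandin", "family", ["prostaglandin", "prostaglandins"]),
    ("R009", "trigeminal nerve", "anatomy", ["trigeminal nerve"]),
    ("R010", "sensitization", "physiology", ["sensitization", "central sensitization"]),
]
_DISEASE_TERMS = [
    ("D001", "diabetes mellitus", ["diabetes mellitus", "diabetes"]),
    ("D002", "rheumatoid arthritis", ["rheumatoid arthritis"]),
    ("D003", "carcinoma", ["carcinoma", "adenocarcinoma"]),
    ("D004", "depression", ["depression"]),
    ("D005", "sepsis", ["sepsis"]),
]

_FILLER = (
    "study cohort samples assay protocol measurements baseline outcomes "
    "profiles datasets controls replicates subjects variance signal matrix "
    "gradient buffer reagent vector"
).split()

_ANATOMY = ["hippocampus", "cerebellum", "liver", "kidney", "macrophage", "plasma"]

_MESH_FILLER = ["Rodentia", "Cell Survival", "Gene Dosage", "Protein Transport"]


def _build_lexicon() -> Lexicon:
    entries = []
    for term_id, name, category, synonyms in _SPECIFIC_TERMS:
        entries.append(LexiconEntry(term_id, name, tuple(synonyms), category, "specific"))
    for term_id, name, category, synonyms in _RELEVANT_TERMS:
        entries.append(LexiconEntry(term_id, name, tuple(synonyms), category, "relevant"))
    return Lexicon(entries)


def _build_disease_lexicon() -> Lexicon:
    entries = [
        LexiconEntry(term_id, name, tuple(synonyms), "disorder", "relevant")
        for term_id, name, synonyms in _DISEASE_TERMS
    ]
    return Lexicon(entries)


# ---------------------------------------------------------------------------
# document assembly


class _DocBuilder:
    """Accumulates sentences per unit and finalizes char offsets."""

    def __init__(self, doc_id: str, fulltext: bool, rng: np.random.Generator):
        self.doc_id = doc_id
        self.fulltext = fulltext
        self.title: list[str] = [_filler_sentence(rng)]
        self.abstract: list[str] = [_filler_sentence(rng) for _ in range(2)]
        self.mesh: list[tuple[str, bool]] = [
            (str(rng.choice(_MESH_FILLER)), bool(rng.random() < 0.3))
        ]
        self.body: list[list[str]] = (
            [[_filler_sentence(rng) for _ in range(2)] for _ in range(int(rng.integers(2, 4)))]
            if fulltext else []
        )

    def unit_sentences(self, section: str, para: int) -> list[str]:
        if section == "title":
            return self.title
        if section == "abstract":
            return self.abstract
        return self.body[para]

    def append_sentence(self, section: str, para: int, sentence: str) -> int:
        unit = self.unit_sentences(section, para)
        unit.append(sentence)
        return len(unit) - 1

    def sentence_offset(self, section: str, para: int, sentence_index: int) -> int:
        unit = self.unit_sentences(section, para)
        return sum(len(s) + 1 for s in unit[:sentence_index])

    def finalize(self) -> Document:
        return Document(
            doc_id=self.doc_id,
            title=" ".join(self.title),
            abstract=" ".join(self.abstract),
            mesh=tuple(self.mesh),
            body=tuple(" ".join(p) for p in self.body),
            source="pmc" if self.fulltext else "medline",
        )


def _filler_sentence(rng: np.random.Generator, n: int | None = None) -> str:
    n = n or int(rng.integers(5, 9))
    words = [str(w) for w in rng.choice(_FILLER, size=n)]
    words[0] = words[0].capitalize()
    return " ".join(words) + "."


def _term_sentence(rng: np.random.Generator, synonym: str) -> tuple[str, int]:
    """A sentence embedding ``synonym``; returns (sentence, char offset)."""
    lead = [str(w) for w in rng.choice(_FILLER, size=int(rng.integers(2, 4)))]
    lead[0] = lead[0].capitalize()
    tail = [str(w) for w in rng.choice(_FILLER, size=int(rng.integers(1, 3)))]
    prefix = " ".join(lead) + " "
    return prefix + synonym + " " + " ".join(tail) + ".", len(prefix)


# ---------------------------------------------------------------------------
# event-chain assembly


@dataclass
class _ChainSpec:
    """A unique chain to be mentioned one or more times."""

    kind: str                      # single | binding | regulation | deep
    reg_type: str                  # regulation flavor for regulation/deep
    participants: list[dict]       # {"entrez": int|None, "surface": str}
    is_true: bool
    signature: str = ""


def _gene_surface(entrez: int | None, idx: int) -> str:
    if entrez is not None:
        return f"TMG{entrez}"
    return f"uprot{idx}"


def _make_participant(spec: dict, span: tuple[int, int]) -> Participant:
    return Participant(
        mention_text=spec["surface"],
        char_span=span,
        entrez_id=spec["entrez"],
        species_taxid=9606 if spec["entrez"] is not None else None,
        homologene_id=(spec["entrez"] % 1000) if spec["entrez"] is not None else None,
    )


_REG_TRIGGERS = {
    "positive_regulation": "induced",
    "negative_regulation": "suppressed",
    "regulation": "modulated",
}


def _event_sentence(
    spec: _ChainSpec, rng: np.random.Generator, negated: bool, speculated: bool,
    anatomy: str,
) -> tuple[str, EventNode]:
    """Build a sentence and its event tree with sentence-local spans."""
    mod = "may have " if speculated else ""

    def place(parts: list[str]) -> tuple[str, list[tuple[int, int]]]:
        spans = []
        pos = 0
        text = ""
        for i, part in enumerate(parts):
            if i:
                text += " "
                pos += 1
            spans.append((pos, pos + len(part)))
            text += part
            pos += len(part)
        return text + ".", spans

    a = spec.participants[0]
    if spec.kind == "single":
        parts = [a["surface"], "expression", "was" if not negated else "was not",
                 "detected", "in", anatomy]
        text, spans = place(parts)
        node = EventNode(
            "gene_expression",
            themes=[_make_participant(a, spans[0])],
            trigger_text="expression", trigger_span=spans[1],
        )
        return text, node
    b = spec.participants[1]
    if spec.kind == "binding":
        verb = "bound" if not negated else "never bound"
        parts = [a["surface"], f"{mod}{verb}", b["surface"], "in", anatomy]
        text, spans = place(parts)
        trig_off = spans[1][0] + len(mod) + (len("never ") if negated else 0)
        node = EventNode(
            "binding",
            themes=[_make_participant(a, spans[0]), _make_participant(b, spans[2])],
            trigger_text="bound", trigger_span=(trig_off, trig_off + 5),
        )
        return text, node
    trigger = _REG_TRIGGERS[spec.reg_type]
    if spec.kind == "regulation":
        parts = [a["surface"], f"{mod}{trigger}", "expression", "of", b["surface"]]
        if negated:
            parts.insert(1, "never")
        text, spans = place(parts)
        trig_idx = 2 if negated else 1
        trig_off = spans[trig_idx][0] + len(mod)
        inner = EventNode(
            "gene_expression",
            themes=[_make_participant(b, spans[-1])],
            trigger_text="expression", trigger_span=spans[trig_idx + 1],
        )
        node = EventNode(
            spec.reg_type, themes=[inner], cause=_make_participant(a, spans[0]),
            trigger_text=trigger, trigger_span=(trig_off, trig_off + len(trigger)),
        )
        return text, node
    # deep: regulation of regulation of expression (3 events)
    parts = [a["surface"], f"{mod}enhanced", "induction", "of", "expression",
             "of", b["surface"]]
    if negated:
        parts.insert(1, "never")
    text, spans = place(parts)
    base = 2 if negated else 1
    trig_off = spans[base][0] + len(mod)
    expr = EventNode("gene_expression", themes=[_make_participant(b, spans[-1])],
                     trigger_text="expression", trigger_span=spans[base + 3])
    mid = EventNode("positive_regulation", themes=[expr],
                    trigger_text="induction", trigger_span=spans[base + 1])
    node = EventNode("positive_regulation", themes=[mid],
                     cause=_make_participant(a, spans[0]),
                     trigger_text="enhanced",
                     trigger_span=(trig_off, trig_off + len("enhanced")))
    return text, node


# ---------------------------------------------------------------------------
# generation


def _beta_params(mean: float, concentration: float = 10.0) -> tuple[float, float]:
    return mean * concentration, (1 - mean) * concentration


def _sample_chain(
    cfg: SimConfig, rng: np.random.Generator,
    gene_pool: np.ndarray, gold: set[int], unnorm_counter: list[int],
) -> _ChainSpec:
    r = rng.random()
    if r < cfg.binding_fraction:
        kind, n_parts = "binding", 2
    elif r < cfg.binding_fraction + cfg.regulation_fraction:
        kind = "deep" if rng.random() < cfg.deep_chain_fraction else "regulation"
        n_parts = 2
    else:
        kind, n_parts = "single", 1
    reg_type = str(rng.choice(["positive_regulation", "negative_regulation",
                               "regulation"]))

    odds = cfg.gold_baseline_prob / (1 - cfg.gold_baseline_prob)
    odds *= cfg.gold_enrichment_factor
    p_gold = odds / (1 + odds)
    wants_gold = bool(rng.random() < p_gold)

    non_gold = [g for g in gene_pool if g not in gold]
    participants: list[dict] = []
    for i in range(n_parts):
        if rng.random() < cfg.unnormalized_rate and not (wants_gold and i == 0):
            unnorm_counter[0] += 1
            participants.append(
                {"entrez": None, "surface": _gene_surface(None, unnorm_counter[0])}
            )
            continue
        if wants_gold and i == 0:
            entrez = int(rng.choice(sorted(gold)))
        else:
            entrez = int(rng.choice(non_gold))
        participants.append({"entrez": entrez, "surface": _gene_surface(entrez, 0)})
    return _ChainSpec(
        kind=kind, reg_type=reg_type, participants=participants,
        is_true=bool(rng.random() < cfg.tp_fraction),
    )


def generate(config: SimConfig) -> Bundle:
    """Generate one synthetic bundle, deterministic per ``config.seed``."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    lexicon = _build_lexicon()
    disease_lexicon = _build_disease_lexicon()

    fulltext = rng.random(cfg.n_docs) < cfg.fulltext_fraction
    builders = [
        _DocBuilder(f"D{i:05d}", bool(fulltext[i]), rng) for i in range(cfg.n_docs)
    ]

    planted_terms: list[dict] = []   # finalized to char spans below
    planted_disease: list[dict] = []

    specific = [e for e in lexicon.entries if e.specificity == "specific"]
    relevant = [e for e in lexicon.entries if e.specificity == "relevant"]

    def plant(entries: list[LexiconEntry], section: str, rate: float,
              sink: list[dict]) -> None:
        # body plants can only land in full-text documents
        eligible = ([i for i in range(cfg.n_docs) if builders[i].fulltext]
                    if section == "body" else list(range(cfg.n_docs)))
        n_target = min(int(round(rate * len(eligible))), len(eligible))
        if n_target == 0:
            return
        chosen = rng.choice(eligible, size=n_target, replace=False)
        for di in sorted(int(x) for x in chosen):
            b = builders[di]
            entry = entries[int(rng.integers(len(entries)))]
            synonym = entry.synonyms[int(rng.integers(len(entry.synonyms)))]
            if section == "mesh":
                b.mesh.append((synonym, False))
                sink.append(dict(doc_id=b.doc_id, term_id=entry.term_id,
                                 synonym=synonym, section="mesh",
                                 paragraph_index=len(b.mesh) - 1,
                                 sentence_index=0, char_span=[0, len(synonym)]))
                continue
            para = int(rng.integers(len(b.body))) if section == "body" else 0
            sentence, offset = _term_sentence(rng, synonym)
            si = b.append_sentence(section, para, sentence)
            sink.append(dict(doc_id=b.doc_id, term_id=entry.term_id,
                             synonym=synonym, section=section,
                             paragraph_index=para, sentence_index=si,
                             _sent_offset=offset))

    plant(specific, "title", cfg.title_specific_rate, planted_terms)
    plant(specific, "abstract", cfg.abstract_specific_rate, planted_terms)
    plant(specific, "mesh", cfg.mesh_specific_rate, planted_terms)
    plant(specific, "body", cfg.body_specific_rate, planted_terms)
    plant(relevant, "title", cfg.title_relevant_rate, planted_terms)
    plant(relevant, "abstract", cfg.abstract_relevant_rate, planted_terms)
    plant(relevant, "mesh", cfg.mesh_relevant_rate, planted_terms)
    plant(relevant, "body", cfg.body_relevant_rate, planted_terms)
    plant(disease_lexicon.entries, "abstract", cfg.disease_rate, planted_disease)

    # --- gene pool, gold set, gene2go
    gene_pool = np.arange(1001, 1001 + cfg.n_genes)
    gold_rng = np.random.default_rng(cfg.gold_seed)  # shared across corpus pairs
    gold_genes = set(
        int(g) for g in gold_rng.choice(gene_pool, size=cfg.n_gold_genes,
                                        replace=False)
    )
    gene2go = []
    for g in gene_pool:
        for k in range(int(rng.integers(1, 4))):
            gene2go.append((int(g), f"GO:{6900 + int(g) % 97 + k:07d}"))

    # --- event chains
    chains: list[_ChainSpec] = []
    mentions: list[EventChainMention] = []
    mutation_records: list[dict] = []
    unnorm_counter = [0]
    true_a, true_b = _beta_params(cfg.confidence_mean_true)
    false_a, false_b = _beta_params(cfg.confidence_mean_false)

    n_events = np.minimum(rng.poisson(cfg.events_per_doc_mean, size=cfg.n_docs),
                          cfg.events_per_doc_max)
    for di in range(cfg.n_docs):
        b = builders[di]
        for _ in range(int(n_events[di])):
            if not chains or rng.random() < cfg.new_chain_prob:
                spec = _sample_chain(cfg, rng, gene_pool, gold_genes, unnorm_counter)
                chains.append(spec)
            else:
                spec = chains[int(rng.integers(len(chains)))]
            negated = bool(rng.random() < cfg.negation_rate)
            speculated = bool(rng.random() < cfg.speculation_rate)
            anatomy = str(rng.choice(_ANATOMY))
            sentence, root = _event_sentence(spec, rng, negated, speculated, anatomy)
            if b.fulltext and rng.random() < 0.5:
                section, para = "body", int(rng.integers(len(b.body)))
            else:
                section, para = "abstract", 0
            si = b.append_sentence(section, para, sentence)
            conf_a, conf_b = (true_a, true_b) if spec.is_true else (false_a, false_b)
            mention = EventChainMention(
                doc_id=b.doc_id, sentence_text=sentence, section=section,
                paragraph_index=para, sentence_index=si, root=root,
                confidence=float(rng.beta(conf_a, conf_b)),
                negated=negated, speculated=speculated,
                anatomy_terms=(anatomy,),
            )
            mentions.append(mention)
            if not spec.signature:
                spec.signature = canonical_signature(mention)

            # optional mutation sentence tied to this mention's first participant
            if rng.random() < cfg.mutation_rate:
                mutation_records.append(
                    _plant_mutation_sentence(b, section, para, spec, rng, cfg)
                )

    documents = [b.finalize() for b in builders]

    # finalize term-plant char spans now that units are complete
    doc_builders = {b.doc_id: b for b in builders}
    for rec in planted_terms + planted_disease:
        if "_sent_offset" in rec:
            b = doc_builders[rec["doc_id"]]
            base = b.sentence_offset(rec["section"], rec["paragraph_index"],
                                     rec["sentence_index"])
            off = base + rec.pop("_sent_offset")
            rec["char_span"] = [off, off + len(rec["synonym"])]

    # --- curation labels over unique chains
    groups = group_event_chains(mentions)
    truth_by_sig = {c.signature: c.is_true for c in chains if c.signature}
    curation = [
        CurationRecord(
            signature=g.signature,
            label="tp" if truth_by_sig.get(g.signature, False) else "fp",
            confidence=g.confidence,
            doc_count=g.doc_count,
        )
        for g in groups
    ]

    retained_ids = sorted(
        {rec["doc_id"] for rec in planted_terms
         if lexicon.by_term_id[rec["term_id"]].specificity == "specific"}
    )

    manifest = {
        "config_seed": cfg.seed,
        "n_docs": cfg.n_docs,
        "planted_terms": planted_terms,
        "planted_disease_terms": planted_disease,
        "retained_doc_ids": retained_ids,
        "groups": {
            g.signature: {"frequency": g.frequency, "doc_count": g.doc_count,
                          "is_true": truth_by_sig.get(g.signature, False)}
            for g in groups
        },
        "mutations": mutation_records,
        "gold_genes": sorted(gold_genes),
    }

    return Bundle(
        config=cfg, documents=documents, lexicon=lexicon,
        disease_lexicon=disease_lexicon, mentions=mentions,
        gold_genes=gold_genes, gene2go=gene2go, curation=curation,
        manifest=manifest,
    )


def _plant_mutation_sentence(
    b: _DocBuilder, section: str, para: int, spec: _ChainSpec,
    rng: np.random.Generator, cfg: SimConfig,
) -> dict:
    """Append a mutation sentence; return its manifest record."""
    residues = "ARNDCQEGHILKMFPSTWYV"
    def mut() -> str:
        return (residues[int(rng.integers(20))]
                + str(int(rng.integers(10, 400)))
                + residues[int(rng.integers(20))])

    protein = spec.participants[0]["surface"]
    style = rng.random()
    patternless = rng.random() < cfg.mutation_patternless_rate
    if patternless:
        # ground-truth association exists but no linking pattern covers it:
        # the linker should miss it (recall loss), never mislink (precision 100)
        m = mut()
        sentence = f"{protein} was examined while {m} appeared separately."
        links, unlinked, prot_spans = [[protein, m]], [], [(0, len(protein))]
    elif style < 0.4:
        m = mut()
        sentence = f"{protein} - {m} was characterized further."
        links = [[protein, m]]
        unlinked = []
        prot_spans = [(0, len(protein))]
    elif style < 0.7:
        ms = [mut(), mut(), mut()]
        prefix = f"Mutations {ms[0]}, {ms[1]} and {ms[2]} for "
        sentence = prefix + protein + " were studied."
        links = [[protein, m] for m in ms]
        unlinked = []
        prot_spans = [(len(prefix), len(prefix) + len(protein))]
    else:
        m = mut()
        sentence = f"The substitution {m} was reported independently."
        links, unlinked, prot_spans = [], [m], []
    si = b.append_sentence(section, para, sentence)
    return {
        "doc_id": b.doc_id, "section": section, "paragraph_index": para,
        "sentence_index": si, "sentence": sentence,
        "proteins": [{"text": protein, "span": list(s)} for s in prot_spans],
        "true_links": links, "true_unlinked": unlinked,
        "patternless": patternless,
    }


def generate_pair(config: SimConfig) -> tuple[Bundle, Bundle]:
    """(focus, background) bundles: same conditions and gold set, background
    without the gold-gene sampling bias (enrichment factor 1)."""
    focus = generate(config)
    background_cfg = replace(config, gold_enrichment_factor=1.0,
                             seed=(config.seed + 104729) % (2**31))
    background = generate(background_cfg)
    return focus, background


# ---------------------------------------------------------------------------
# serialization


def write_bundle(bundle: Bundle, out_dir) -> dict[str, str]:
    """Write the bundle's file set; returns a name -> path map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    from .corpus import write_documents_jsonl

    paths["documents"] = str(out / "documents.jsonl")
    write_documents_jsonl(bundle.documents, paths["documents"])
    paths["lexicon"] = str(out / "lexicon.tsv")
    save_lexicon(bundle.lexicon, paths["lexicon"])
    paths["disease_lexicon"] = str(out / "disease_lexicon.tsv")
    save_lexicon(bundle.disease_lexicon, paths["disease_lexicon"])
    paths["events"] = str(out / "events.json")
    save_event_mentions(bundle.mentions, paths["events"])
    paths["gold_genes"] = str(out / "gold_genes.txt")
    Path(paths["gold_genes"]).write_text(
        "".join(f"{g}\n" for g in sorted(bundle.gold_genes))
    )
    paths["gene2go"] = str(out / "gene2go.tsv")
    with open(paths["gene2go"], "w") as fh:
        fh.write("entrez_id\tgo_id\n")
        for entrez, go in bundle.gene2go:
            fh.write(f"{entrez}\t{go}\n")
    paths["curation"] = str(out / "curation_labels.tsv")
    with open(paths["curation"], "w") as fh:
        fh.write("signature\tlabel\tconfidence\tdoc_count\n")
        for r in bundle.curation:
            fh.write(f"{r.signature}\t{r.label}\t{r.confidence!r}\t{r.doc_count}\n")
    paths["manifest"] = str(out / "manifest.json")
    Path(paths["manifest"]).write_text(json.dumps(bundle.manifest, indent=1))
    return paths


# ---------------------------------------------------------------------------
# manifest verification


def _stage(expected: set, recovered: set) -> dict:
    tp = len(expected & recovered)
    precision = tp / len(recovered) if recovered else 1.0
    recall = tp / len(expected) if expected else 1.0
    return {"precision": 100.0 * precision, "recall": 100.0 * recall,
            "pass": precision == 1.0 and recall == 1.0}


def manifest_check(bundle: Bundle) -> dict:
    """Re-run the pipeline on the bundle and compare with the manifest.

    Reports per-stage precision/recall; stages built to be exact (term
    matching, retrieval, grouping) must come back at 100/100.  Mutation-linker
    recall drops below 100 exactly when patternless sentences were planted.
    """
    manifest = bundle.manifest
    report: dict[str, dict] = {}

    # term matching
    expected = {
        (r["doc_id"], r["term_id"], r["section"], r["paragraph_index"],
         tuple(r["char_span"]))
        for r in manifest["planted_terms"]
    }
    recovered = set()
    for doc in bundle.documents:
        for tm in match_terms(doc, bundle.lexicon):
            recovered.add((doc.doc_id, tm.term_id, tm.section,
                           tm.paragraph_index, tm.char_span))
    report["term_matching"] = _stage(expected, recovered)

    # disease matching
    expected_d = {
        (r["doc_id"], r["term_id"], r["section"], r["paragraph_index"],
         tuple(r["char_span"]))
        for r in manifest["planted_disease_terms"]
    }
    recovered_d = set()
    for doc in bundle.documents:
        for tm in match_terms(doc, bundle.disease_lexicon):
            recovered_d.add((doc.doc_id, tm.term_id, tm.section,
                             tm.paragraph_index, tm.char_span))
    report["disease_matching"] = _stage(expected_d, recovered_d)

    # retrieval
    retained, _, _ = build_corpus(bundle.documents, bundle.lexicon)
    report["retrieval"] = _stage(set(manifest["retained_doc_ids"]),
                                 {d.doc_id for d in retained})

    # grouping: signatures with exact frequency and doc_count
    groups = group_event_chains(bundle.mentions)
    expected_g = {
        (sig, meta["frequency"], meta["doc_count"])
        for sig, meta in manifest["groups"].items()
    }
    recovered_g = {(g.signature, g.frequency, g.doc_count) for g in groups}
    report["grouping"] = _stage(expected_g, recovered_g)

    # mutation detection + linking
    exp_links: set = set()
    exp_mutations: set = set()
    rec_links: set = set()
    rec_mutations: set = set()
    for i, rec in enumerate(manifest["mutations"]):
        for prot, m in rec["true_links"]:
            exp_links.add((i, prot, m))
        for m in rec["true_links"]:
            exp_mutations.add((i, m[1]))
        for m in rec["true_unlinked"]:
            exp_mutations.add((i, m))
        muts = find_mutations(rec["sentence"])
        for m in muts:
            rec_mutations.add((i, m.normalized))
        proteins = [Participant(mention_text=p["text"], char_span=tuple(p["span"]))
                    for p in rec["proteins"]]
        links, _unlinked = link_mutations(rec["sentence"], proteins, muts)
        for link in links:
            rec_links.add((i, link.protein.mention_text, link.mutation.normalized))
    report["mutation_detection"] = _stage(exp_mutations, rec_mutations)
    report["mutation_linking"] = _stage(exp_links, rec_links)

    report["pass"] = all(
        v["pass"] for k, v in report.items()
        if isinstance(v, dict) and not (k == "mutation_linking"
                                        and any(r["patternless"]
                                                for r in manifest["mutations"]))
    )
    return report
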