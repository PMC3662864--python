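# topicminer

Build a topic-specific catalogue of molecular interactions from literature
annotations, and support its manual curation with statistics.

## The problem

Manually curated molecular-interaction databases are accurate but take years
to build. Text mining can pre-populate such a database in weeks, if three
problems are solved:

1. **Corpus building.** Find the documents that are actually about the topic
   (here: pain research), not merely mention it, and rank them by relevance.
2. **Interaction extraction and grouping.** The same interaction is mentioned
   thousands of times across the literature with different wording; mentions
   must be deduplicated into unique interactions with their textual context
   (negation, speculation, anatomy, GO terms, point mutations) preserved.
3. **Curation support.** A human curator cannot read everything; statistics
   over extractor confidence and document counts tell them where to look
   first, and agreement/enrichment statistics measure how well it works.

`topicminer` implements this pipeline for sectioned literature records
(title, abstract, MeSH descriptors, body paragraphs) carrying per-sentence
event-chain annotations from an upstream biomedical event extractor.

## The model

**Dictionary matching.** A weighted lexicon of topic terms — *specific* terms
(weight 2, synonymous with the topic) and *relevant* terms (weight 1, merely
associated) — is matched case-sensitively at token boundaries, leftmost-longest.
A document is retained iff it matches at least one specific term. Its
relevance score is the sum over term mentions of
`specificity weight × section weight`, with section weights title 2,
abstract 1, MeSH 1, body 0.25.

**Event chains.** An event chain is a nested molecular event from one sentence,
up to three linked events over the nine GENIA-style event types. Mentions are
grouped under a canonical signature: participants identified by Entrez Gene ID
where normalized (surface text otherwise), binding themes sorted (binding is
symmetric), regulation cause/theme order preserved. A group records mention
frequency, distinct-document count and the maximum extractor confidence.

**Context.** Groups carry aggregated negation/speculation polarity, anatomy
mentions, GO annotations, detected point mutations linked to in-sentence
proteins by priority-ranked textual patterns, and a 5–100 *relevancy score*
for each (topic term, event mention) pair — same sentence scores 75–100 by
trigger proximity, with lower tiers for same paragraph (60), title (55),
MeSH (50), abstract (45), adjacent body paragraph (30), and a distance decay
down to 5 beyond that. Per group these aggregate into an overall topic
relevancy: the mean over the group's documents of
`Σ_terms weight × (best score − 50)/50` over terms scoring above 50, banded
as low (0), medium (≤1), high (>1).

**Curation statistics.** Confusion metrics from evaluation counts, Cohen's
kappa between curation rounds, Fisher's exact test for gold-gene-set
enrichment, precision stratified by confidence and document count, and a
binomial GLM (logit link) of curated correctness on extractor confidence
whose root gives a triage threshold.

**Synthetic corpora.** A deterministic generator produces full input bundles
(documents, lexicons, event mentions, gold genes, curation labels) from
pairwise-disjoint vocabularies, with every planted fact recorded in a
manifest; `manifest_check` re-runs the pipeline against the manifest and must
come back exact on stages built to be exact.

## Worked example

Matching a small lexicon against one document (matching is case-sensitive:
the capitalized title form needs its own synonym):

```python
from topicminer import Lexicon, LexiconEntry
from topicminer.corpus import Document, match_terms, score_document

lex = Lexicon([
    LexiconEntry("T1", "neuropathic pain",
                 ("neuropathic pain", "Neuropathic pain"), "pain type", "specific"),
    LexiconEntry("T2", "dorsal root ganglion",
                 ("dorsal root ganglion", "DRG"), "anatomy", "relevant"),
])
doc = Document(
    doc_id="PM1",
    title="Neuropathic pain after nerve injury",
    abstract="Expression changed in the dorsal root ganglion after ligation.",
    mesh=(("Pain", True),),
)
matches = match_terms(doc, lex)
for m in matches:
    print(m)
print(score_document(matches, lex))
```

prints

```
TermMatch(term_id='T1', matched_synonym='Neuropathic pain', section='title', paragraph_index=0, sentence_index=0, char_span=(0, 16))
TermMatch(term_id='T2', matched_synonym='dorsal root ganglion', section='abstract', paragraph_index=0, sentence_index=0, char_span=(26, 46))
DocumentScore(overall=5.0, per_category={'pain type': 4.0, 'anatomy': 1.0}, per_term={'T1': 4.0, 'T2': 1.0})
```

(specific in title: 2×2 = 4; relevant in abstract: 1×1 = 1).

Mutation detection and linking:

```python
from topicminer.events import Participant
from topicminer.mutation_link import find_mutations, link_mutations

s = "Overexpression of p53 - R175H blocked apoptosis."
prot = Participant("p53", char_span=(s.index("p53"), s.index("p53") + 3))
links, unlinked = link_mutations(s, [prot], find_mutations(s))
for l in links:
    print(l.protein.mention_text, l.mutation.normalized, l.pattern_id)
```

prints `p53 R175H 1` (pattern 1: `<protein> - <mutation>`).

The full pipeline runs from the command line. Generate a synthetic bundle and
run every stage over it:

```bash
topicminer simulate --seed 7 --n-docs 100 --out fixtures
cat > config.yaml <<'YAML'
lexicon: fixtures/lexicon.tsv
documents: fixtures/documents.jsonl
events: fixtures/events.json
curation_labels: fixtures/curation_labels.tsv
gene2go: fixtures/gene2go.tsv
out_dir: out
YAML
topicminer run --config config.yaml
```

prints

```
[corpus] 69/100 documents retained
[group-events] 96 unique chains from 198 mentions
[link-mutations] 0 mutation links
[score-relevancy] 96 groups scored
[curate-stats] 119 curation records
```

and writes `scores.tsv`, `groups.tsv`/`groups.json`, `mutations.tsv`,
`relevancy.tsv`, `curation_report.json` and `run_log.json` under `out/`.
The top of `out/groups.tsv`:

```
signature	class	frequency	doc_count	confidence	polarity	speculation	self_interaction
gene_expression(G:1032)	single_event	7	7	0.37302	all_positive	none	0
gene_expression(G:1001)	single_event	6	5	0.302693	mixed	mixed	0
```

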