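# Methods

This note records the model implemented by `topicminer`, the parameter values
it ships with, the scope of the synthetic generator, and the numerical
choices behind the statistics. Every empirical number cited here is computed
by the test suite or by `scripts/acceptance.py`; nothing is asserted from
memory.

## Corpus model

Documents are sectioned records: title, abstract, a list of MeSH descriptors
(each flagged major/minor), and zero or more body paragraphs. Each MeSH
descriptor and each body paragraph is its own matching unit with its own
paragraph index.

**Term matching** is dictionary-based: case-sensitive, anchored at token
boundaries (a token boundary is any position not flanked by `[A-Za-z0-9]` on
the relevant side), leftmost-longest. Leftmost-longest is implemented as a
single regex alternation with synonyms sorted by decreasing length;
non-overlapping scanning then yields exactly the leftmost-longest segmentation.
Case variants must be listed as synonyms. An optional abbreviation pass
registers parenthetical abbreviations following a matched term as
document-local synonyms and rescans.

**Retrieval and scoring.** A document enters the corpus iff it matches at
least one *specific* term (weight 2); *relevant* terms (weight 1) contribute
to scores but not retrieval. The document score is
`Σ_mentions weight(term) × weight(section)` with section weights
title 2, abstract 1, MeSH 1, body 0.25. These weights are configuration, not
constants; the defaults are the study conditions. Known limitation: full-text
documents score higher than abstract-only documents simply by having more
matchable text; the 0.25 body weight attenuates but does not remove this.

**Group comparison.** `compare_mesh_groups` compares score distributions
between MeSH-major and MeSH-minor documents with a rank-sum test. The
reported Z is the tie-corrected normal approximation of the Mann–Whitney U
statistic; the p-value is computed exactly for small untied samples and
asymptotically otherwise. The test suite verifies the p-value against full
permutation enumeration for group sizes ≤ 6.

## Event chains

An event chain is one to three linked events over nine event types. Typed
constraints are enforced at construction: only binding takes multiple themes;
only the three regulation types take an event as theme or carry a cause.

The grouping key is a prefix-notation serialization of the event tree.
Participants are identified by Entrez Gene ID when normalized (`G:1234`) and
by lowercased surface text otherwise (`U:p38`); gene symbols are never used
as identity because they are ambiguous. Binding themes are sorted before
serialization — numerically by Entrez ID when all themes are normalized,
case-insensitively by text otherwise, normalized before unnormalized in mixed
cases — so binding is symmetric by construction. Regulation cause/theme order
is preserved: swapping them is a different chain. Groups aggregate mention
frequency, distinct-document count, maximum confidence, and
negation/speculation polarity (`all_positive` / `mixed` / `all_negative`;
a mixed group is a potential literature contradiction).

## Mutations

Detection normalizes substitutions to wNm (one-letter codes): `A123T`,
`Ala123Thr`, `A123 to T`, `Ala123 to Thr`. The bare one-letter form requires
a position of at least two digits; single-digit forms collide with gene,
histone and cell-marker names (H2A, S100B, CD4 T) too often for a
precision-oriented tool. This trades away recall on legitimate single-digit
positions; the three-letter and verbose forms still cover them.

Linking is a priority-ranked list of gap-regex rules between a mutation and a
protein mention in the same sentence (`<protein> - <mutation>`,
`<mutation> of/in/for <protein>`, with enumeration rules distributing
comma/`and`-separated mutation runs over a trailing protein). Lowest rule id
wins; each mutation links at most once. A nearest-protein-within-5-tokens
fallback exists but is off by default: the contract is that an unmatched
mutation is reported unlinked, never guessed. Cross-sentence anaphora is out
of scope. Rules are data and can be replaced from a TSV file.

## Relevancy

Each (term match, event mention) pair in a document scores 5–100:

| configuration | score |
|---|---|
| same sentence | 75 + round(25 · (1 − d/max(L−1, 1))) for token distance d to the trigger, sentence length L |
| same paragraph, different sentence | 60 |
| term in title | 55 |
| term in MeSH | 50 |
| term in abstract (event elsewhere) | 45 |
| adjacent body paragraph (gap 1) | 30 |
| farther (gap g ≥ 2, or no common distance axis, g = 2) | max(5, 25 − 5·(g−1)) |

The tier values live in a frozen `RelevancyTiers` object and can be
overridden. The 30-point tier applies exactly to adjacent body paragraphs;
from gap 2 the decay formula takes over (60, 30, 20, 15, 10, 5 — monotone in
distance). This reconstruction choice keeps the score monotone and matches
all documented scoring examples.

Overall topic relevancy of a group:
`(1/|D|) Σ_d Σ_{t: s_td > 50} w_t (s_td − 50)/50`, where D is the group's
document set, s_td the best link score of term t in document d, and w_t the
specificity weight. Bands: low (= 0), medium (> 0, ≤ 1), high (> 1). The
disease variant is identical but unweighted and reported per disease term.

## Curation statistics

* **Confusion metrics** are percentages at full precision; a metric whose
  denominator is unavailable is `None`, never 0. Published tables sometimes
  truncate rather than round (e.g. an F score of 82.758 printed as 82.7); the
  acceptance tests compare with the same convention.
* **Cohen's kappa** is computed from round marginals:
  p_e = p(tp,before)·p(tp,after) + p(fp,before)·p(fp,after). One published
  intra-round kappa is inconsistent with this formula and its own marginals
  (recomputation gives ≈ 0.63, not the printed 0.43) and is excluded from
  acceptance.
* **Fisher's exact test** reports the sample odds ratio a·d/(b·c) (inf/nan at
  zero margins), the two-sided exact p-value, a display string that switches
  to `<2.2e-16` when p underflows the double floor, and the conditional-MLE
  odds ratio for tables with total ≤ 10,000 (the CMLE root-solve is too slow
  for corpus-scale tables and the sample OR is what large-table consumers
  use). The suite verifies the p-value against brute-force hypergeometric
  enumeration for all 2×2 tables with row margins ≤ 12.
* **Triage model**: binomial GLM with logit link of curated correctness on
  extractor confidence. The triage threshold is −intercept/slope, reported
  only when the slope is positive and significant (|z| > 1.96); single-label
  input and complete separation raise `TriageFitError` rather than fitting
  silently. At n = 2000 the fit recovers a known threshold of 0.25 within
  ±0.03 (verified under a fixed seed).

## Synthetic generator

The generator's purpose is pipeline verification, not linguistic realism.
Sentences are template-generated token strings; the realism is structural:
sections with character offsets, nested event trees with sentence-local
spans, negation/speculation flags, confidence mixtures, mutation sentences.

Key design points:

* **Disjoint vocabularies.** Lexicon terms, disease terms, filler words, gene
  surface forms, anatomy terms and template scaffolding share no tokens, so
  every planted mention is recovered exactly once and planted counts are
  exact ground truth.
* **Manifest.** Every planted fact (term spans, retained document ids, group
  signatures with frequency/doc-count/truth, mutation associations, gold
  genes) is recorded; `manifest_check` re-runs matching, retrieval, grouping
  and mutation detection/linking and reports per-stage precision/recall.
  Stages built to be exact must return 100/100. Optionally the generator
  plants "patternless" mutation sentences whose true association no linking
  rule covers; these lower linker recall (and are excluded from the overall
  pass flag) while precision must stay 100 — the designed failure mode of a
  precision-oriented linker.
* **Confidence mixture.** Mention confidence is Beta(10m, 10(1−m)) with mean
  m = 0.30 for true chains and 0.10 for false ones — the separation the
  triage model exploits. These means are study conditions, not tuning knobs.
* **Gold-gene enrichment.** Each new chain mentions a gold gene with
  probability derived from baseline odds multiplied by the configured
  enrichment factor, so the expected odds ratio between a focus corpus and a
  factor-1 background equals the factor by construction. A corpus pair shares
  its gold set via a dedicated `gold_seed`. Across 20 seeded pairs of 250
  documents the mean log odds ratio stays within ±0.2 (bound set a priori) of
  log 2 for the default factor 2.
* **Problem sizes.** Defaults (300 documents, ~3 events/document, 60 genes,
  12 gold genes) keep a bundle under a second to generate; the acceptance
  suite uses 150–400-document bundles, which yield 500–1500 event mentions.
  Generation is fully deterministic per seed.

## Limitations

* The matcher is strictly dictionary-based: no morphological variants, no
  disambiguation; case variants must be enumerated. Abbreviation capture only
  handles the parenthetical definition pattern.
* Sentence splitting is a regex heuristic (terminator + capital/digit); it
  will split on abbreviation periods followed by capitals.
* Mutation linking is sentence-bound and pattern-bound by design; recall on
  out-of-sentence associations is zero.
* The relevancy tier table is a reconstruction (documented above); the tier
  values are exposed as configuration for recalibration.
* Corpus-scale published figures (hundreds of thousands of documents, the
  corpus-level rank-sum Z, the empirical relevancy distribution, the 28%
  production triage threshold) depend on external resources and are not
  reproducible here; they are covered by property-based tests and seeded
  parameter-recovery experiments instead.
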