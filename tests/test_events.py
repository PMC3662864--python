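import json

import pytest

from topicminer.events import (
    EventChainMention,
    EventNode,
    GroupedEventChain,
    Participant,
    annotate_go,
    canonical_signature,
    classify_polarity,
    group_event_chains,
    load_event_mentions,
    mention_from_dict,
    mention_to_dict,
    save_event_mentions,
    summarize_context,
    write_groups_json,
    write_groups_tsv,
)


def P(text, entrez=None):
    return Participant(mention_text=text, entrez_id=entrez)


def mention(root, doc_id="d1", confidence=0.5, negated=False, speculated=False,
            anatomy=()):
    return EventChainMention(
        doc_id=doc_id, sentence_text="s", section="abstract",
        paragraph_index=0, sentence_index=0, root=root,
        confidence=confidence, negated=negated, speculated=speculated,
        anatomy_terms=tuple(anatomy),
    )


class TestValidation:
    def test_unknown_event_type(self):
        with pytest.raises(ValueError, match="unknown event type"):
            EventNode("splicing", [P("x")])

    def test_only_binding_takes_multiple_themes(self):
        EventNode("binding", [P("a"), P("b")])  # fine
        with pytest.raises(ValueError, match="binding"):
            EventNode("gene_expression", [P("a"), P("b")])

    def test_only_regulation_takes_cause(self):
        EventNode("positive_regulation", [P("a")], cause=P("b"))  # fine
        with pytest.raises(ValueError, match="cause"):
            EventNode("phosphorylation", [P("a")], cause=P("b"))

    def test_only_regulation_takes_event_theme(self):
        inner = EventNode("gene_expression", [P("a")])
        EventNode("regulation", [inner])  # fine
        with pytest.raises(ValueError, match="event theme"):
            EventNode("localization", [inner])

    def test_theme_required(self):
        with pytest.raises(ValueError, match="theme"):
            EventNode("binding", [])

    def test_chain_depth_capped_at_three_events(self):
        e1 = EventNode("gene_expression", [P("a")])
        e2 = EventNode("positive_regulation", [e1])
        e3 = EventNode("negative_regulation", [e2])
        mention(e3)  # three events: fine
        e4 = EventNode("regulation", [e3])
        with pytest.raises(ValueError, match="events"):
            mention(e4)

    def test_confidence_range(self):
        with pytest.raises(ValueError, match="confidence"):
            mention(EventNode("binding", [P("a"), P("b")]), confidence=1.5)

    def test_entrez_id_positive(self):
        with pytest.raises(ValueError, match="entrez_id"):
            Participant("a", entrez_id=0)


class TestSignature:
    def test_binding_theme_order_irrelevant_normalized(self):
        m1 = mention(EventNode("binding", [P("A", 10), P("B", 2)]))
        m2 = mention(EventNode("binding", [P("B", 2), P("A", 10)]))
        assert canonical_signature(m1) == canonical_signature(m2)
        assert canonical_signature(m1) == "binding(G:2,G:10)"

    def test_binding_unnormalized_sorted_case_insensitively(self):
        m = mention(EventNode("binding", [P("zeta"), P("Alpha")]))
        assert canonical_signature(m) == "binding(U:alpha,U:zeta)"

    def test_normalized_sorts_before_unnormalized(self):
        m = mention(EventNode("binding", [P("aaa"), P("Z", 99)]))
        assert canonical_signature(m) == "binding(G:99,U:aaa)"

    def test_cause_theme_asymmetry_preserved(self):
        a, b = P("a", 1), P("b", 2)
        m1 = mention(EventNode("regulation", [a], cause=b))
        m2 = mention(EventNode("regulation", [b], cause=a))
        assert canonical_signature(m1) != canonical_signature(m2)
        assert canonical_signature(m1) == "regulation(G:1;cause=G:2)"

    def test_nested_chain_signature(self):
        inner = EventNode("gene_expression", [P("trkA", 59)])
        m = mention(EventNode("positive_regulation", [inner], cause=P("NGF", 18)))
        assert canonical_signature(m) == \
            "positive_regulation(gene_expression(G:59);cause=G:18)"

    def test_surface_text_case_folded_only_when_unnormalized(self):
        m1 = mention(EventNode("gene_expression", [P("TrkA")]))
        m2 = mention(EventNode("gene_expression", [P("trka")]))
        assert canonical_signature(m1) == canonical_signature(m2)

    def test_signature_idempotent_under_roundtrip(self):
        m = mention(EventNode("binding", [P("A", 3), P("b")]))
        again = mention_from_dict(mention_to_dict(m))
        assert canonical_signature(again) == canonical_signature(m)


class TestGrouping:
    def test_groups_merge_same_signature(self):
        ms = [
            mention(EventNode("binding", [P("A", 1), P("B", 2)]), doc_id="d1",
                    confidence=0.3),
            mention(EventNode("binding", [P("B", 2), P("A", 1)]), doc_id="d2",
                    confidence=0.9),
            mention(EventNode("gene_expression", [P("C", 3)]), doc_id="d1"),
        ]
        groups = group_event_chains(ms)
        assert len(groups) == 2
        top = groups[0]
        assert top.frequency == 2 and top.doc_count == 2
        assert top.confidence == pytest.approx(0.9)

    def test_sorted_by_frequency_then_signature(self):
        ms = [mention(EventNode("gene_expression", [P("b", 2)])),
              mention(EventNode("gene_expression", [P("a", 1)]))]
        groups = group_event_chains(ms)
        assert [g.signature for g in groups] == \
            ["gene_expression(G:1)", "gene_expression(G:2)"]

    def test_chain_class_and_self_interaction(self):
        single = GroupedEventChain("s", [mention(EventNode("gene_expression", [P("a", 1)]))])
        pair = GroupedEventChain("s", [mention(EventNode("binding", [P("a", 1), P("b", 2)]))])
        homo = GroupedEventChain("s", [mention(EventNode("binding", [P("a", 1), P("a", 1)]))])
        deep = GroupedEventChain("s", [mention(
            EventNode("regulation", [EventNode("binding", [P("a", 1), P("b", 2)])],
                      cause=P("c", 3)))])
        assert single.chain_class == "single_event"
        assert pair.chain_class == "molecular_interaction"
        assert deep.chain_class == "multi" and deep.participant_count == 3
        assert homo.is_self_interaction and not pair.is_self_interaction

    def test_polarity_and_speculation_aggregation(self):
        root = EventNode("gene_expression", [P("a", 1)])
        all_pos = GroupedEventChain("s", [mention(root), mention(root)])
        mixed = GroupedEventChain("s", [mention(root), mention(root, negated=True)])
        all_neg = GroupedEventChain("s", [mention(root, negated=True)])
        spec = GroupedEventChain("s", [mention(root, speculated=True)])
        assert classify_polarity(all_pos) == ("all_positive", "none")
        assert classify_polarity(mixed)[0] == "mixed"
        assert classify_polarity(all_neg)[0] == "all_negative"
        assert classify_polarity(spec)[1] == "all"


class TestAnnotateGo:
    def test_fills_normalized_participants_only(self):
        m = mention(EventNode("binding", [P("A", 1), P("b")]))
        groups = group_event_chains([m])
        annotate_go(groups, [(1, "GO:0001"), (1, "GO:0002"), (2, "GO:0003")])
        parts = sorted(m.root.themes, key=lambda p: p.mention_text)
        assert parts[0].go_terms == {"GO:0001", "GO:0002"}
        assert parts[1].go_terms == set()

    def test_goslim_mapping_added(self):
        m = mention(EventNode("gene_expression", [P("A", 1)]))
        groups = group_event_chains([m])
        annotate_go(groups, {1: ["GO:0001"]}, goslim={"GO:0001": "GO:SLIM1"})
        assert m.root.themes[0].go_terms == {"GO:0001", "GO:SLIM1"}


class TestSummarize:
    def test_anatomy_counts_over_mentions(self):
        root = EventNode("gene_expression", [P("a", 1)])
        groups = group_event_chains([
            mention(root, anatomy=("dorsal horn",)),
            mention(root, anatomy=("dorsal horn", "sciatic nerve")),
        ])
        ctx = summarize_context(groups)
        assert ctx["anatomy"] == {"dorsal horn": 2, "sciatic nerve": 1}

    def test_repeated_event_type_counts_once_non_redundant(self):
        inner = EventNode("positive_regulation", [EventNode("gene_expression", [P("a", 1)])])
        root = EventNode("positive_regulation", [inner])
        ctx = summarize_context(group_event_chains([mention(root)]))
        cell = ctx["event_types"]["positive_regulation"]["all"]
        assert cell == {"non_redundant": 1, "total": 2}


class TestSerialization:
    def test_round_trip_file(self, tmp_path):
        ms = [
            mention(EventNode("positive_regulation",
                              [EventNode("binding", [P("A", 1), P("b")])],
                              cause=P("C", 3)),
                    confidence=0.77, negated=True, anatomy=("spinal cord",)),
        ]
        path = tmp_path / "events.json"
        save_event_mentions(ms, path)
        back = load_event_mentions(path)
        assert len(back) == 1
        assert canonical_signature(back[0]) == canonical_signature(ms[0])
        assert back[0].negated and back[0].confidence == pytest.approx(0.77)
        assert back[0].anatomy_terms == ("spinal cord",)

    def test_write_groups_tsv_and_json(self, tmp_path):
        groups = group_event_chains([
            mention(EventNode("binding", [P("a", 1), P("b", 2)]), confidence=0.4),
        ])
        tsv, js = tmp_path / "g.tsv", tmp_path / "g.json"
        write_groups_tsv(groups, tsv)
        write_groups_json(groups, js)
        lines = tsv.read_text().splitlines()
        assert lines[0].split("\t")[0] == "signature"
        assert lines[1].split("\t")[0] == "binding(G:1,G:2)"
        payload = json.loads(js.read_text())
        assert payload[0]["frequency"] == 1
        assert payload[0]["mentions"][0]["confidence"] == pytest.approx(0.4)


class TestBundleProperties:
    """Grouping invariants on a large synthetic mention set."""

    def test_bundle_has_over_1000_mentions(self, large_bundle):
        assert len(large_bundle.mentions) >= 1000

    def test_frequencies_sum_to_mention_count(self, large_bundle):
        groups = group_event_chains(large_bundle.mentions)
        assert sum(g.frequency for g in groups) == len(large_bundle.mentions)

    def test_grouping_invariant_under_permutation(self, large_bundle):
        groups = group_event_chains(large_bundle.mentions)
        reversed_groups = group_event_chains(list(reversed(large_bundle.mentions)))
        assert [(g.signature, g.frequency) for g in groups] == \
            [(g.signature, g.frequency) for g in reversed_groups]

    def test_doc_count_never_exceeds_frequency(self, large_bundle):
        for g in group_event_chains(large_bundle.mentions):
            assert 1 <= g.doc_count <= g.frequency

    def test_group_confidence_is_max_over_mentions(self, large_bundle):
        for g in group_event_chains(large_bundle.mentions)[:50]:
            assert g.confidence == max(m.confidence for m in g.mentions)
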