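"""Standoff parsing, graph extraction, stratified sampling, dataset merging."""

import numpy as np
import pytest

from ddegk.errors import DanglingReference, DuplicateTag, SpanMismatch
from ddegk.graphs import TypeVocabulary, validate_event_graph
from ddegk.standoff import (SamplingSpec, events_to_graphs, merge_datasets,
                            node_count_bin, parse_standoff, stratified_sample)
from ddegk.synth import default_schema, generate

TEXT = "Bmi-1 is overexpressed and promotes tumorigenesis in mice."
A1 = "T1\tProtein 0 5\tBmi-1\nT5\tCancer 36 49\ttumorigenesis\n"
A2 = ("T2\tGene_expression 9 22\toverexpressed\n"
      "T3\tPositive_regulation 27 35\tpromotes\n"
      "E1\tGene_expression:T2 Theme:T1 Cause:E2\n"
      "E2\tPositive_regulation:T3 Theme:T5\n"
      "M1\tNegation E1\n")


class TestParse:
    def test_entity_line(self):
        doc = parse_standoff(TEXT, A1, A2, "doc1")
        t1 = doc.text_bound("T1")
        assert (t1.type_label, t1.span, t1.surface) == ("Protein", (0, 5), "Bmi-1")

    def test_event_line(self):
        doc = parse_standoff(TEXT, A1, A2, "doc1")
        e1 = doc.event("E1")
        assert e1.event_type == "Gene_expression"
        assert e1.trigger_id == "T2"
        assert ("Theme", "T1") in e1.args

    def test_modifier_line_skipped(self, caplog):
        doc = parse_standoff(TEXT, A1, A2, "doc1")
        assert doc.event("M1") is None  # negation modifier never becomes an event
        assert len(doc.events) == 2

    def test_span_mismatch_raises(self):
        with pytest.raises(SpanMismatch):
            parse_standoff(TEXT, "T1\tProtein 0 5\tWRONG\n", "", "doc1")

    def test_dangling_reference_raises(self):
        with pytest.raises(DanglingReference):
            parse_standoff(TEXT, A1,
                           "T2\tGene_expression 9 22\toverexpressed\n"
                           "E1\tGene_expression:T2 Theme:T99\n", "doc1")

    def test_discontinuous_span(self):
        text = "abc def ghi"
        a1 = "T1\tProtein 0 3;8 11\tabc ghi\n"
        doc = parse_standoff(text, a1, "", "doc1")
        assert doc.text_bound("T1").surface == "abc ghi"


class TestEventsToGraphs:
    def test_single_top_level_graph_with_nested_cause(self):
        doc = parse_standoff(TEXT, A1, A2, "doc1")
        graphs = events_to_graphs(doc)
        assert len(graphs) == 1  # E2 is nested inside E1
        (g,) = graphs
        assert g.n_nodes == 4 and len(g.edges) == 3
        assert g.principal_type == "Gene_expression"
        cause = next(e for e in g.edges if e.role_label == "Cause")
        assert g.node(cause.target).kind == "trigger"  # trigger-trigger edge

    def test_simple_event(self):
        doc = parse_standoff("Bmi-1 expr", "T1\tProtein 0 5\tBmi-1\n",
                             "T2\tGene_expression 6 10\texpr\n"
                             "E1\tGene_expression:T2 Theme:T1\n", "d")
        (g,) = events_to_graphs(doc)
        assert g.n_nodes == 2 and len(g.edges) == 1

    def test_shared_subevent_duplicated_across_parents(self):
        a2 = ("T2\tGene_expression 9 22\toverexpressed\n"
              "T3\tPositive_regulation 27 35\tpromotes\n"
              "T6\tNegative_regulation 9 22\toverexpressed\n"
              "E1\tGene_expression:T2 Cause:E2\n"
              "E2\tPositive_regulation:T3 Theme:T5\n"
              "E3\tNegative_regulation:T6 Cause:E2\n")
        doc = parse_standoff(TEXT, A1, a2, "doc1")
        graphs = events_to_graphs(doc)
        assert len(graphs) == 2
        # both parents inline an isomorphic copy of E2's 2-node subgraph
        assert sorted(g.n_nodes for g in graphs) == [3, 3]

    def test_emitted_graphs_always_validate(self):
        doc = parse_standoff(TEXT, A1, A2, "doc1")
        graphs = events_to_graphs(doc)
        vocab = TypeVocabulary.from_graphs(graphs)
        assert all(validate_event_graph(g, vocab).ok for g in graphs)

    def test_numbered_roles_collapse_flag(self):
        a2 = ("T2\tGene_expression 9 22\toverexpressed\n"
              "E1\tGene_expression:T2 Theme:T1 Theme2:T5\n")
        doc = parse_standoff(TEXT, A1, a2, "doc1")
        (kept,) = events_to_graphs(doc)
        assert {e.role_label for e in kept.edges} == {"Theme", "Theme2"}
        (collapsed,) = events_to_graphs(doc, collapse_numbered_roles=True)
        assert {e.role_label for e in collapsed.edges} == {"Theme"}


class TestStratifiedSample:
    def _population(self, n=100, seed=0):
        # 60/40 across two principal types via family weights
        schema = default_schema()
        graphs, labels = generate(schema, 300, seed=seed)
        keep_a = [g for g, l in zip(graphs, labels) if l == "Binding"][:60]
        keep_b = [g for g, l in zip(graphs, labels)
                  if l == "Gene_expression"][:40]
        return keep_a + keep_b

    def test_proportional_quotas(self):
        pop = self._population()
        picked = stratified_sample(pop, SamplingSpec(target_n=50, seed=1))
        counts = {}
        for g in picked:
            counts[g.principal_type] = counts.get(g.principal_type, 0) + 1
        assert len(picked) == 50
        assert abs(counts["Binding"] - 30) <= 1
        assert abs(counts["Gene_expression"] - 20) <= 1

    def test_rare_type_removed(self):
        pop = self._population()
        rare = [g for g in generate(default_schema(), 300, seed=9)[0]
                if g.principal_type == "Positive_regulation"][:9]
        picked = stratified_sample(pop + rare,
                                   SamplingSpec(target_n=120, seed=0))
        assert all(g.principal_type != "Positive_regulation" for g in picked)

    def test_full_population_identity(self):
        pop = self._population()
        picked = stratified_sample(pop, SamplingSpec(target_n=len(pop)))
        assert len(picked) == len(pop)

    def test_seed_reproducible_and_counts_stable(self):
        pop = self._population()
        s1 = stratified_sample(pop, SamplingSpec(target_n=40, seed=5))
        s2 = stratified_sample(pop, SamplingSpec(target_n=40, seed=5))
        assert [g.doc_id for g in s1] == [g.doc_id for g in s2]
        s3 = stratified_sample(pop, SamplingSpec(target_n=40, seed=6))

        def counts(sample):
            out = {}
            for g in sample:
                key = (g.principal_type, node_count_bin(g.n_nodes))
                out[key] = out.get(key, 0) + 1
            return out

        assert counts(s1) == counts(s3)  # quotas identical, membership varies

    def test_no_duplicates(self):
        pop = self._population()
        picked = stratified_sample(pop, SamplingSpec(target_n=50, seed=3))
        ids = [g.doc_id for g in picked]
        assert len(set(ids)) == len(ids)


def test_node_count_bins_partition():
    assert [node_count_bin(n) for n in (2, 3, 4, 5, 6, 7, 15)] == \
        ["2", "3", "4", "5", "6", "7+", "7+"]


class TestMerge:
    def test_union_with_tags(self, small_graphs):
        graphs, _ = small_graphs
        merged = merge_datasets([("a", graphs[:5]), ("b", graphs[5:10])])
        assert len(merged) == 10
        assert {g.dataset_tag for g in merged} == {"a", "b"}

    def test_shared_type_label_merges_in_vocabulary(self, small_graphs):
        graphs, _ = small_graphs
        merged = merge_datasets([("a", graphs[:5]), ("b", graphs[:5:][:5])])
        vocab = TypeVocabulary.from_graphs(merged)
        assert len(vocab.node_types) == len(set(vocab.node_types))

    def test_empty_dataset_skipped(self, small_graphs, caplog):
        graphs, _ = small_graphs
        merged = merge_datasets([("a", graphs[:3]), ("b", [])])
        assert len(merged) == 3

    def test_duplicate_tag_rejected(self, small_graphs):
        graphs, _ = small_graphs
        with pytest.raises(DuplicateTag):
            merge_datasets([("a", graphs[:2]), ("a", graphs[2:4])])
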