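"""Topology catalog: walk/recurrence predicates, canonical classification,
and the shape census."""
import itertools

import pytest
from hypothesis import given, settings, strategies as st

from actmotifs.patterns import (classify_topology, default_catalog,
                                enumerate_sequential_words, has_recurrence,
                                is_sequential, label_types, load_catalog,
                                walk_decomposition, UNCATALOGED)
from actmotifs.types import TYPE_CODES, parse_pattern

P = parse_pattern


@pytest.mark.parametrize("text,expected", [
    ("F>S", True),
    ("F>S,S>E", True),
    ("F>S,F>E", False),
    ("R>C,F>E", False),
])
def test_is_sequential(text, expected):
    assert is_sequential(P(text)) is expected


@pytest.mark.parametrize("text,expected", [
    ("F>S,S>F", True),        # cycle: the user returns to the first type
    ("F>S,S>E", False),       # chain through three distinct types
    ("F>S,F>E", True),        # two processes sharing their source type
    ("R>C,F>E", False),       # detached processes, nothing shared
])
def test_has_recurrence(text, expected):
    assert has_recurrence(P(text)) is expected


@pytest.mark.parametrize("text,name", [
    ("F>S", "Line"),
    ("F>S,S>F", "Ring"),
    ("C>F,F>T", "Chain"),
    ("F>S,S>F,F>S", "Triple_line"),
    ("F>S,S>F,F>E", "Star_pre"),
    ("S>F,F>E,E>F", "Star_pos"),
    ("T>C,C>F,F>T", "Triad"),
    ("O>S,S>F,F>E", "Triple_chain"),
    ("F>S,S>F,F>S,S>F", "Four_times_line"),
    ("F>S,F>S", "Ring_n"),
    ("F>S,F>E", "Chain_n1"),
    ("F>S,E>S", "Chain_n2"),
    ("F>S,E>F", "Chain_n3"),
    ("F>S,F>S,S>F", "Triple_line_n1"),
    ("F>S,S>F,S>F", "Triple_line_n2"),
    ("E>F,S>F,F>S", "Star_pos_n1"),
    ("F>E,F>S,S>F", "Star_pos_n2"),
    ("F>S,E>F,S>E", "Triad_n"),
    ("R>C,F>E", UNCATALOGED),      # disconnected two-process pair
    ("F>S,F>S,F>S", UNCATALOGED),  # three parallel repeats: not a shape
])
def test_classify_topology(text, name):
    assert classify_topology(P(text)) == name


def test_walk_decomposition_splits_into_maximal_processes():
    assert walk_decomposition(P("R>C,C>O,F>E")) == [P("R>C,C>O"), P("F>E")]
    assert walk_decomposition(P("F>S,E>F,S>E")) == [
        P("F>S"), P("E>F"), P("S>E")]


class TestCensus:
    def test_sequential_word_counts(self):
        assert len(enumerate_sequential_words(1)) == 1
        assert len(enumerate_sequential_words(2)) == 2
        assert len(enumerate_sequential_words(3)) == 5
        assert len(enumerate_sequential_words(4)) == 14

    def test_brute_force_word_enumeration_agrees(self):
        # independent oracle: filter all label words over A..D directly
        for k in (2, 3, 4):
            words = set()
            for w in itertools.product("ABCD", repeat=k + 1):
                if any(a == b for a, b in zip(w, w[1:])):
                    continue
                # canonical: labels appear in first-appearance order
                seen = []
                for x in w:
                    if x not in seen:
                        seen.append(x)
                if seen == sorted(seen) and seen[0] == "A" and all(
                        ord(b) - ord(a) == 1 for a, b in zip(seen, seen[1:])):
                    words.add("".join(w))
            assert words == set(enumerate_sequential_words(k))

    def test_high_order_sequential_topology_total(self):
        catalog = default_catalog()
        high = [t for t in catalog.sequential() if t.n_edges >= 3]
        assert len(high) == 19

    def test_two_edge_nonsequential_shapes_are_the_four_connected_ones(self):
        # oracle: enumerate all connected non-walk 2-edge canonical shapes
        catalog = default_catalog()
        shapes = set()
        for e1 in itertools.permutations("ABC", 2):
            for e2 in itertools.permutations("ABCD", 2):
                p = (e1, e2)
                if is_sequential(p):
                    continue
                nodes1, nodes2 = set(e1), set(e2)
                if not nodes1 & nodes2:
                    continue
                from actmotifs.patterns import canonical_form
                shapes.add(canonical_form(p))
        assert len(shapes) == 4
        assert shapes == {t.canonical for t in catalog.nonsequential(2)}

    def test_typed_pattern_census(self):
        catalog = default_catalog()
        expected = {"Line": 42, "Ring": 42, "Chain": 210, "Triad": 210,
                    "Triple_chain": 840}
        for name, count in expected.items():
            assert catalog.get(name).typed_pattern_count(7) == count

    def test_recurrence_flags_from_templates(self):
        catalog = default_catalog()
        false_names = {"Line", "Chain", "Triple_chain"}
        for name in false_names:
            assert not catalog.get(name).recurrence
        for name in ("Ring", "Triple_line", "Four_times_line", "Star_pre",
                     "Star_pos", "Triad"):
            assert catalog.get(name).recurrence
        # every non-sequential shape shares a type across processes
        assert all(t.recurrence for t in catalog.nonsequential())


@given(st.data())
@settings(max_examples=200, derandomize=True)
def test_classification_invariant_under_type_substitution(data):
    """Any injective relabeling of the types preserves the topology class."""
    catalog = default_catalog()
    template = data.draw(st.sampled_from(catalog.templates))
    labels = sorted({x for e in template.edges for x in e})
    codes = data.draw(st.permutations(TYPE_CODES))
    mapping = dict(zip(labels, codes))
    pattern = tuple((mapping[a], mapping[b]) for a, b in template.edges)
    assert catalog.classify(pattern) == template.name


def test_label_types_aligns_display_labels():
    catalog = default_catalog()
    # Star_pos S>F,F>E,E>F: walk S->F->E->F, central (cycled) type is F = A
    types = label_types(P("S>F,F>E,E>F"), catalog.get("Star_pos"))
    assert types == {"B": "S", "A": "F", "C": "E"}
    # Star_pre cycle first: F>S,S>F,F>E has central F = A, branch end E = C
    types = label_types(P("F>S,S>F,F>E"), catalog.get("Star_pre"))
    assert types == {"A": "F", "B": "S", "C": "E"}


def test_catalog_restricts_max_edges():
    small = load_catalog(max_edges=2)
    assert all(t.n_edges <= 2 or not t.sequential for t in small)
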