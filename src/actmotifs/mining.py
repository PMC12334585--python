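"""Candidate detection and occurrence counting over daily sequences.

A daily sequence "contains" a pattern when the pattern's typed edge list is
an order-preserving subsequence of the sequence's transition list — edges
need not be temporally adjacent (intermediate activities may be skipped) nor
topologically connected (two detached processes may co-occur). One rule
covers both cases because activity types encode node identity.

Occurrence counting is per-sequence containment: each daily sequence
contributes at most 1 to a pattern's count, so a pattern's occurrence is the
number of distinct daily sequences containing it. Two code paths produce the
same table:

``count_occurrences``
    brute-force enumeration of all index combinations — the semantics anchor,
    kept as an oracle;
``fast_count``
    a single left-to-right sweep per sequence over distinct typed-prefix
    patterns (boolean reachability flags suffice for containment), bounded by
    O(L x number of prefix states) instead of binomial subset enumeration.
"""
from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .patterns import TopologyCatalog, default_catalog, is_sequential
from .types import DailySequence, Pattern

__all__ = [
    "CandidateSpace",
    "OccurrenceTable",
    "contains",
    "extract_candidates",
    "extract_candidates_brute",
    "count_occurrences",
    "fast_count",
]


@dataclass(frozen=True)
class CandidateSpace:
    """Which typed patterns are eligible for counting.

    Defaults: sequential walks of 1–4 edges with at most 4 distinct types,
    plus the cataloged connected non-sequential shapes of 2–3 edges.
    """

    max_edges: int = 4
    max_types: int = 4
    include_nonsequential: bool = True
    nonseq_edge_counts: tuple[int, ...] = (2, 3)
    catalog: TopologyCatalog = field(default_factory=default_catalog)

    def admits(self, pattern: Pattern) -> bool:
        k = len(pattern)
        if not 1 <= k <= self.max_edges:
            return False
        if len({x for e in pattern for x in e}) > self.max_types:
            return False
        if is_sequential(pattern):
            return True
        if not self.include_nonsequential or k not in self.nonseq_edge_counts:
            return False
        t = self.catalog.template_of(pattern)
        return t is not None and not t.sequential


@dataclass
class OccurrenceTable:
    """Pattern -> number of distinct daily sequences containing it."""

    counts: dict[Pattern, int]
    n_sequences_total: int
    #: number of sequences with at least k transitions, keyed by k
    n_sequences_by_min_length: dict[int, int]

    @property
    def n_patterns(self) -> int:
        """Number of distinct candidate structures observed."""
        return len(self.counts)

    def __getitem__(self, pattern: Pattern) -> int:
        return self.counts.get(pattern, 0)


def contains(sequence: DailySequence, pattern: Pattern) -> bool:
    """True iff ``pattern``'s edges are an order-preserving subsequence of
    the sequence's transitions (indices strictly increasing)."""
    transitions = sequence.transitions()
    it = iter(transitions)
    return all(edge in it for edge in pattern)


def extract_candidates_brute(sequence: DailySequence,
                             space: CandidateSpace | None = None
                             ) -> set[Pattern]:
    """Oracle path: enumerate every index combination of 1..max_edges
    transitions and keep the distinct admissible patterns."""
    space = space or CandidateSpace()
    transitions = sequence.transitions()
    found: set[Pattern] = set()
    for k in range(1, min(space.max_edges, len(transitions)) + 1):
        for idx in itertools.combinations(range(len(transitions)), k):
            pattern = tuple(transitions[i] for i in idx)
            if space.admits(pattern):
                found.add(pattern)
    return found


def extract_candidates(sequence: DailySequence,
                       space: CandidateSpace | None = None) -> set[Pattern]:
    """Fast path: sweep the transition list once, maintaining the set of
    distinct subsequence patterns (typed prefixes) seen so far; a new
    transition extends every shorter prefix and starts a new one. Sets give
    the boolean reachability flags containment needs. Prefixes growing past
    ``max_types`` distinct types are pruned (type count never decreases)."""
    space = space or CandidateSpace()
    max_edges, max_types = space.max_edges, space.max_types
    prefixes: set[Pattern] = set()
    for edge in sequence.transitions():
        new: set[Pattern] = set()
        for p in prefixes:
            if len(p) < max_edges:
                q = p + (edge,)
                if len({x for e in q for x in e}) <= max_types:
                    new.add(q)
        new.add((edge,))
        prefixes |= new
    return {p for p in prefixes if space.admits(p)}


def _tally(sequences: Iterable[DailySequence],
           space: CandidateSpace,
           extractor) -> OccurrenceTable:
    counts: Counter[Pattern] = Counter()
    by_min_len: Counter[int] = Counter()
    total = 0
    for seq in sequences:
        total += 1
        for k in range(1, min(seq.n_transitions, space.max_edges) + 1):
            by_min_len[k] += 1
        counts.update(extractor(seq, space))
    return OccurrenceTable(counts=dict(counts), n_sequences_total=total,
                           n_sequences_by_min_length=dict(sorted(by_min_len.items())))


def count_occurrences(sequences: Iterable[DailySequence],
                      space: CandidateSpace | None = None) -> OccurrenceTable:
    """Brute-force occurrence counting (the semantics anchor)."""
    return _tally(sequences, space or CandidateSpace(),
                  extract_candidates_brute)


def fast_count(sequences: Iterable[DailySequence],
               space: CandidateSpace | None = None) -> OccurrenceTable:
    """Sweep-based occurrence counting; identical output to
    :func:`count_occurrences` by construction (property-tested)."""
    return _tally(sequences, space or CandidateSpace(), extract_candidates)
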