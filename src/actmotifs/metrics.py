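"""Motif selection by dual frequency thresholds, and the MCR/COR metrics.

Two support thresholds are derived as fixed fractions of the analyzed
sequence count N: a high one (default 0.5% of N) for sequential patterns
with at most two edges, which any length-2 day can realize, and a low one
(default 0.1% of N) for sequential patterns with three or more edges and for
all non-sequential patterns, which only the minority of long days can
realize. A pattern whose occurrence reaches its class threshold is a motif.

MCR (motif coverage ratio) = Nc / Na: sequences containing at least one
motif of a group, over sequences long enough to contain one (for a group
whose smallest member has k edges, days with at least k transitions).

COR (cumulative occurrence ratio) = Cs / Ca: summed occurrences of selected
motifs over summed occurrences of all motifs in a scope.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

from .mining import OccurrenceTable, contains
from .patterns import TopologyCatalog, default_catalog, is_sequential, label_types
from .types import ConfigError, DailySequence, Pattern

__all__ = [
    "ThresholdPair",
    "MotifSet",
    "MetricResult",
    "compute_thresholds",
    "select_motifs",
    "topology_occurrence",
    "mcr",
    "cor",
    "type_at_label",
]

#: Default threshold fractions (f_high_order, f_low_order): the fraction for
#: high-order/non-sequential patterns and for low-order sequential patterns.
DEFAULT_FRACTIONS = (0.001, 0.005)


@dataclass(frozen=True)
class ThresholdPair:
    """Support thresholds by pattern class (floor of fraction x N, >= 1)."""

    low_order_threshold: int
    high_order_threshold: int
    fractions: tuple[float, float]
    n_total: int

    def for_pattern(self, pattern: Pattern) -> int:
        """Low-order sequential patterns (<= 2 edges) face the low-order
        (larger-fraction) threshold; everything else the high-order one."""
        if is_sequential(pattern) and len(pattern) <= 2:
            return self.low_order_threshold
        return self.high_order_threshold


def compute_thresholds(n_total: int,
                       fractions: tuple[float, float] = DEFAULT_FRACTIONS
                       ) -> ThresholdPair:
    """Floor-rounded fraction-of-N thresholds, clamped to at least 1."""
    if n_total <= 0:
        raise ConfigError("n_total must be positive")
    f_high, f_low = fractions
    for f in fractions:
        if not 0 < f < 1:
            raise ConfigError("threshold fractions must be in (0, 1)")
    return ThresholdPair(
        low_order_threshold=max(1, math.floor(f_low * n_total)),
        high_order_threshold=max(1, math.floor(f_high * n_total)),
        fractions=(f_high, f_low),
        n_total=n_total,
    )


@dataclass
class MotifSet:
    """Patterns passing their class threshold, with per-topology views."""

    motifs: dict[Pattern, int]
    thresholds: ThresholdPair
    catalog: TopologyCatalog = field(default_factory=default_catalog)

    def __contains__(self, pattern: Pattern) -> bool:
        return pattern in self.motifs

    def __len__(self) -> int:
        return len(self.motifs)

    def by_topology(self) -> dict[str, list[Pattern]]:
        grouped: dict[str, list[Pattern]] = {}
        for p in sorted(self.motifs):
            grouped.setdefault(self.catalog.classify(p), []).append(p)
        return grouped

    def in_topologies(self, names: Iterable[str]) -> list[Pattern]:
        wanted = set(names)
        return [p for p in sorted(self.motifs)
                if self.catalog.classify(p) in wanted]


def select_motifs(table: OccurrenceTable, thresholds: ThresholdPair,
                  catalog: TopologyCatalog | None = None) -> MotifSet:
    """Keep every pattern whose occurrence count is >= its class threshold
    (boundary counts are kept; the convention lives in ThresholdPair)."""
    motifs = {p: c for p, c in table.counts.items()
              if c >= thresholds.for_pattern(p)}
    return MotifSet(motifs=dict(sorted(motifs.items())), thresholds=thresholds,
                    catalog=catalog or default_catalog())


@dataclass(frozen=True)
class MetricResult:
    """A ratio metric with its numerator/denominator bookkeeping.

    ``value`` is None when the denominator is zero (undefined, not an error).
    """

    numerator: int
    denominator: int
    group: str = ""

    @property
    def value(self) -> float | None:
        if self.denominator == 0:
            return None
        return self.numerator / self.denominator

    @property
    def defined(self) -> bool:
        return self.denominator > 0


def topology_occurrence(sequences: Sequence[DailySequence],
                        patterns: Iterable[Pattern]) -> int:
    """Number of distinct sequences containing at least one of ``patterns``
    (deduplicated: a day with several of them counts once)."""
    pats = sorted(set(patterns))
    if not pats:
        return 0
    singles = {p[0] for p in pats if len(p) == 1}
    longer = [p for p in pats if len(p) > 1]
    n = 0
    for seq in sequences:
        transitions = seq.transitions()
        if singles and not singles.isdisjoint(transitions):
            n += 1
        elif any(contains(seq, p) for p in longer):
            n += 1
    return n


def mcr(sequences: Sequence[DailySequence],
        group: Iterable[Pattern],
        min_edges: int | None = None,
        name: str = "") -> MetricResult:
    """Motif coverage ratio Nc/Na for a motif group.

    Na counts sequences with at least ``min_edges`` transitions; by default
    that is the smallest edge count in the group, so a mixed group (e.g. all
    high-order motifs) is measured against the days that could contain its
    shortest member.
    """
    group = list(group)
    if not group:
        raise ConfigError("mcr needs a non-empty motif group")
    k = min_edges if min_edges is not None else min(len(p) for p in group)
    na = sum(1 for s in sequences if s.n_transitions >= k)
    nc = topology_occurrence(sequences, group)
    return MetricResult(numerator=nc, denominator=na, group=name)


def cor(target: Iterable[Pattern], scope: Iterable[Pattern],
        table: OccurrenceTable, name: str = "") -> MetricResult:
    """Cumulative occurrence ratio Cs/Ca of ``target`` motifs within the
    ``scope`` motif collection; target must be a subset of scope."""
    scope = set(scope)
    target = set(target)
    if not target <= scope:
        raise ConfigError("COR target must be a subset of its scope")
    cs = sum(table[p] for p in target)
    ca = sum(table[p] for p in scope)
    return MetricResult(numerator=cs, denominator=ca, group=name)


def type_at_label(pattern: Pattern, label: str,
                  catalog: TopologyCatalog | None = None) -> str:
    """The concrete activity type at a template position (e.g. the central
    node A of a Star_pre/Star_pos/Triad motif); used to build COR selectors
    like "all Star_pos motifs with Food at the centre"."""
    catalog = catalog or default_catalog()
    template = catalog.template_of(pattern)
    if template is None:
        raise ConfigError("pattern is not in the topology catalog")
    return label_types(pattern, template)[label]
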