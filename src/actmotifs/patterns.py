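"""Typed temporal patterns and the topology catalog.

A pattern is a temporally ordered list of typed transitions (edges). Because
node identity *is* the activity type, two patterns are equal iff their edge
lists are equal — there is no abstract-node matching at count time. Shape
classes ("topologies") abstract types away: relabeling the types of a pattern
by first appearance yields a canonical label word that indexes the catalog.

Sequential topologies are temporal walks (each edge starts where the previous
one ended); they are enumerated exhaustively up to four edges and four
distinct labels. Non-sequential topologies are not walks but are weakly
connected — they model the co-occurrence of two or more detached activity
processes sharing at least one type — and are loaded from a data file.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

import yaml

from .types import ConfigError, Edge, Pattern, parse_pattern

__all__ = [
    "TopologyTemplate",
    "TopologyCatalog",
    "is_sequential",
    "has_recurrence",
    "classify_topology",
    "canonical_form",
    "walk_decomposition",
    "label_types",
    "load_catalog",
    "enumerate_sequential_words",
    "UNCATALOGED",
]

UNCATALOGED = "uncataloged"

#: Field-standard names for sequential walk words (node-visit words with labels
#: in first-appearance order). Remaining four-edge words get systematic names.
SEQUENTIAL_NAMES: dict[str, str] = {
    "AB": "Line",
    "ABA": "Ring",
    "ABC": "Chain",
    "ABAB": "Triple_line",
    "ABAC": "Star_pre",
    "ABCB": "Star_pos",
    "ABCA": "Triad",
    "ABCD": "Triple_chain",
    "ABABA": "Four_times_line",
}

#: Display edge templates for named sequential topologies. Labels follow the
#: published schematics (e.g. the central node of Star_pre/Star_pos/Triad is
#: A), which for Star_pos differs from first-appearance labels.
SEQUENTIAL_DISPLAY_EDGES: dict[str, list[str]] = {
    "Line": ["A>B"],
    "Ring": ["A>B", "B>A"],
    "Chain": ["A>B", "B>C"],
    "Triple_line": ["A>B", "B>A", "A>B"],
    "Star_pre": ["A>B", "B>A", "A>C"],
    "Star_pos": ["B>A", "A>C", "C>A"],
    "Triad": ["A>B", "B>C", "C>A"],
    "Triple_chain": ["A>B", "B>C", "C>D"],
    "Four_times_line": ["A>B", "B>A", "A>B", "B>A"],
}

_LABELS = "ABCD"


@dataclass(frozen=True)
class TopologyTemplate:
    """An untyped shape class over abstract labels.

    ``edges`` are in temporal order with labels as drawn in the schematics
    (the central node of star/triad shapes is A); ``canonical`` is the same
    edge list relabeled by first appearance, the key used for matching.
    """

    name: str
    edges: tuple[Edge, ...]
    sequential: bool
    recurrence: bool

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def n_nodes(self) -> int:
        return len({x for e in self.edges for x in e})

    @property
    def canonical(self) -> Pattern:
        return canonical_form(self.edges)

    def typed_pattern_count(self, n_types: int = 7) -> int:
        """Number of typed patterns with this shape: falling factorial
        n_types * (n_types-1) * ... over the distinct labels."""
        count = 1
        for i in range(self.n_nodes):
            count *= n_types - i
        return count


def is_sequential(pattern: Pattern) -> bool:
    """True iff the edges form a temporal walk (dst of edge i = src of edge
    i+1 for every consecutive pair)."""
    return all(a[1] == b[0] for a, b in zip(pattern, pattern[1:]))


def walk_decomposition(pattern: Pattern) -> list[Pattern]:
    """Split the temporal edge list into maximal temporal walks (the
    pattern's component "processes")."""
    if not pattern:
        return []
    walks: list[list[Edge]] = [[pattern[0]]]
    for edge in pattern[1:]:
        if walks[-1][-1][1] == edge[0]:
            walks[-1].append(edge)
        else:
            walks.append([edge])
    return [tuple(w) for w in walks]


def has_recurrence(pattern: Pattern) -> bool:
    """True iff some activity type repeats: more than once along the node
    visit list of a walk, or appearing in two different processes."""
    if is_sequential(pattern):
        visits = [pattern[0][0]] + [e[1] for e in pattern]
        return len(set(visits)) < len(visits)
    processes = walk_decomposition(pattern)
    node_sets = [{x for e in w for x in e} for w in processes]
    for i, j in itertools.combinations(range(len(node_sets)), 2):
        if node_sets[i] & node_sets[j]:
            return True
    return False


def is_weakly_connected(pattern: Pattern) -> bool:
    """True iff the underlying multigraph of the edges is weakly connected."""
    if not pattern:
        return False
    nodes = {x for e in pattern for x in e}
    seen = {pattern[0][0]}
    frontier = True
    while frontier:
        frontier = False
        for a, b in pattern:
            if (a in seen) != (b in seen):
                seen |= {a, b}
                frontier = True
    return seen == nodes


def canonical_form(pattern: Pattern) -> Pattern:
    """Relabel node types by first appearance (A, B, C, D) in temporal edge
    order; patterns with the same shape map to the same canonical edge list."""
    relabel: dict[str, str] = {}
    out = []
    for a, b in pattern:
        for x in (a, b):
            if x not in relabel:
                relabel[x] = _LABELS[len(relabel)]
        out.append((relabel[a], relabel[b]))
    return tuple(out)


def walk_word(pattern: Pattern) -> str:
    """Node-visit word of a sequential pattern in canonical labels."""
    canon = canonical_form(pattern)
    return canon[0][0] + "".join(e[1] for e in canon)


def label_types(pattern: Pattern, template: TopologyTemplate) -> dict[str, str]:
    """Map the template's display labels to the pattern's concrete types by
    positional alignment of the edge lists (e.g. the Star_pos central label A
    maps to the type at the centre of the concrete pattern)."""
    if canonical_form(pattern) != template.canonical:
        raise ValueError(f"pattern does not match template {template.name}")
    mapping: dict[str, str] = {}
    for (la, lb), (ta, tb) in zip(template.edges, pattern):
        mapping[la] = ta
        mapping[lb] = tb
    return mapping


def enumerate_sequential_words(n_edges: int, max_labels: int = 4) -> list[str]:
    """All canonical adjacent-distinct label words of length ``n_edges + 1``
    with labels in first-appearance order and at most ``max_labels`` distinct
    labels. These are exactly the sequential shape classes with n_edges edges.
    """
    words = ["A"]
    for _ in range(n_edges):
        nxt = []
        for w in words:
            used = sorted(set(w))
            options = used + [_LABELS[len(used)]] if len(used) < max_labels else used
            for lab in options:
                if lab != w[-1]:
                    nxt.append(w + lab)
        words = nxt
    return sorted(set(words))


def _word_to_edges(word: str) -> Pattern:
    return tuple(zip(word, word[1:]))


class TopologyCatalog:
    """The closed set of shape classes eligible for counting.

    Sequential templates are generated (walk words, 1..max_edges edges);
    non-sequential templates come from the packaged data file (2–3 edges by
    default). ``classify`` is total over the candidate space and returns
    :data:`UNCATALOGED` for anything else rather than guessing.
    """

    def __init__(self, templates: list[TopologyTemplate],
                 max_edges: int = 4) -> None:
        self.max_edges = max_edges
        self.templates = templates
        self._by_canonical = {t.canonical: t for t in templates}
        if len(self._by_canonical) != len(templates):
            raise ConfigError("duplicate canonical shapes in catalog")
        self._by_name = {t.name: t for t in templates}

    def __iter__(self):
        return iter(self.templates)

    def __len__(self) -> int:
        return len(self.templates)

    def get(self, name: str) -> TopologyTemplate:
        return self._by_name[name]

    def sequential(self, n_edges: int | None = None) -> list[TopologyTemplate]:
        return [t for t in self.templates if t.sequential
                and (n_edges is None or t.n_edges == n_edges)]

    def nonsequential(self, n_edges: int | None = None) -> list[TopologyTemplate]:
        return [t for t in self.templates if not t.sequential
                and (n_edges is None or t.n_edges == n_edges)]

    def classify(self, pattern: Pattern) -> str:
        t = self._by_canonical.get(canonical_form(pattern))
        return t.name if t is not None else UNCATALOGED

    def template_of(self, pattern: Pattern) -> TopologyTemplate | None:
        return self._by_canonical.get(canonical_form(pattern))


def _sequential_templates(max_edges: int) -> list[TopologyTemplate]:
    out = []
    for k in range(1, max_edges + 1):
        for word in enumerate_sequential_words(k):
            name = SEQUENTIAL_NAMES.get(word, f"Seq{k}_{word}")
            display = SEQUENTIAL_DISPLAY_EDGES.get(name)
            edges = (tuple(parse_edge(e) for e in display) if display
                     else _word_to_edges(word))
            out.append(TopologyTemplate(
                name=name,
                edges=edges,
                sequential=True,
                recurrence=len(set(word)) < len(word),
            ))
    return out


def parse_edge(text: str) -> Edge:
    src, dst = text.split(">")
    return (src.strip(), dst.strip())


def load_catalog(max_edges: int = 4,
                 include_nonsequential: bool = True,
                 nonseq_path=None) -> TopologyCatalog:
    """Build the full topology catalog.

    Parameters
    ----------
    max_edges
        Maximum number of edges for sequential walk templates (1..4).
    include_nonsequential
        Whether to load the non-sequential shape file.
    nonseq_path
        Override path for the non-sequential catalog (defaults to the
        packaged ``data/topology_catalog.yaml``).
    """
    if not 1 <= max_edges <= 4:
        raise ConfigError("max_edges must be in 1..4")
    templates = _sequential_templates(max_edges)
    if include_nonsequential:
        if nonseq_path is None:
            text = (resources.files("actmotifs") / "data"
                    / "topology_catalog.yaml").read_text()
        else:
            with open(nonseq_path) as fh:
                text = fh.read()
        raw = yaml.safe_load(text)
        for entry in raw["nonsequential"]:
            edges = tuple(parse_edge(e) for e in entry["edges"])
            if is_sequential(edges):
                raise ConfigError(
                    f"non-sequential template {entry['name']} is a walk")
            if not is_weakly_connected(edges):
                raise ConfigError(
                    f"non-sequential template {entry['name']} is disconnected")
            tpl = TopologyTemplate(name=entry["name"], edges=edges,
                                   sequential=False,
                                   recurrence=has_recurrence(edges))
            templates.append(tpl)
    return TopologyCatalog(templates, max_edges=max_edges)


@lru_cache(maxsize=1)
def default_catalog() -> TopologyCatalog:
    return load_catalog()


def classify_topology(pattern: Pattern,
                      catalog: TopologyCatalog | None = None) -> str:
    """Name of the unique catalog template whose canonical label word matches
    the pattern's first-appearance relabeling; :data:`UNCATALOGED` otherwise.
    """
    catalog = catalog or default_catalog()
    return catalog.classify(pattern)
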