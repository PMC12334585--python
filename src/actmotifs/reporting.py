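"""Analysis-table exports: activity-type distributions of selected motifs.

Pure functions of (motif set, occurrence table). Three table families:

* two-node topologies (Line, Ring, Triple_line, ...): a 7x7 occurrence
  matrix with rows = type at node A, columns = type at node B, plus the
  per-node marginal vectors (exactly the row/column sums);
* three-node topologies (Chain, Star_pre, Star_pos, Triad, ...): long-format
  records keyed by the types at template nodes A, B, C;
* two-edge non-sequential motifs: the co-occurrence matrix of the earlier
  transition (A>B) versus the later one (C>D), with the bridging-mode block
  labels (type of B, type of C).
"""
from __future__ import annotations

from pathlib import Path

import pandas as pd

from .metrics import MotifSet
from .mining import OccurrenceTable
from .patterns import label_types
from .types import TYPE_CODES

__all__ = [
    "two_node_matrix",
    "three_node_table",
    "nonseq_two_edge_table",
    "export_distribution_tables",
]


def two_node_matrix(motifs: MotifSet, table: OccurrenceTable,
                    topology: str) -> pd.DataFrame:
    """7x7 occurrence matrix of a two-node topology's motifs
    (rows: node A type, columns: node B type)."""
    template = motifs.catalog.get(topology)
    mat = pd.DataFrame(0, index=list(TYPE_CODES), columns=list(TYPE_CODES))
    for p in motifs.in_topologies([topology]):
        types = label_types(p, template)
        mat.loc[types["A"], types["B"]] += table[p]
    return mat


def three_node_table(motifs: MotifSet, table: OccurrenceTable,
                     topology: str) -> pd.DataFrame:
    """Long-format (type_A, type_B, type_C, count) records for a three-node
    topology's motifs."""
    template = motifs.catalog.get(topology)
    rows = []
    for p in motifs.in_topologies([topology]):
        types = label_types(p, template)
        rows.append({"type_A": types["A"], "type_B": types["B"],
                     "type_C": types["C"], "count": table[p]})
    return pd.DataFrame(rows, columns=["type_A", "type_B", "type_C", "count"])


def nonseq_two_edge_table(motifs: MotifSet,
                          table: OccurrenceTable) -> pd.DataFrame:
    """Co-occurrence records of two-edge non-sequential motifs: earlier
    transition, later transition, and the bridging mode (end of the earlier
    process, start of the later one). The (type_B, type_C) pairs tile the
    table into at most 49 bridging-mode blocks."""
    rows = []
    for name in ("Ring_n", "Chain_n1", "Chain_n2", "Chain_n3"):
        for p in motifs.in_topologies([name]):
            (a, b), (c, d) = p
            rows.append({"transition_1": f"{a}>{b}", "transition_2": f"{c}>{d}",
                         "type_B": b, "type_C": c, "topology": name,
                         "count": table[p]})
    return pd.DataFrame(rows, columns=["transition_1", "transition_2",
                                       "type_B", "type_C", "topology",
                                       "count"])


def export_distribution_tables(motifs: MotifSet, table: OccurrenceTable,
                               outdir) -> list[Path]:
    """Write every non-empty distribution table to ``outdir``; returns the
    written paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    present = set(motifs.by_topology())

    for template in motifs.catalog:
        if template.name not in present or not template.sequential:
            continue
        if template.n_nodes == 2 and template.n_edges <= 3:
            mat = two_node_matrix(motifs, table, template.name)
            path = outdir / f"two_node_{template.name}_matrix.csv"
            mat.to_csv(path, index_label="type_A")
            marg = pd.DataFrame({"node_A": mat.sum(axis=1),
                                 "node_B": mat.sum(axis=0)})
            mpath = outdir / f"two_node_{template.name}_marginals.csv"
            marg.to_csv(mpath, index_label="type")
            written += [path, mpath]
        elif template.n_nodes == 3 and template.n_edges == 3:
            tab = three_node_table(motifs, table, template.name)
            path = outdir / f"three_node_{template.name}.csv"
            tab.to_csv(path, index=False)
            written.append(path)

    nonseq = nonseq_two_edge_table(motifs, table)
    if len(nonseq):
        path = outdir / "nonseq_two_edge_cooccurrence.csv"
        nonseq.to_csv(path, index=False)
        written.append(path)
    return written
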