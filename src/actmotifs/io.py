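"""Reading and writing check-in tables, category maps, and sequence stores.

Raw check-in tables are delimited text with a header row; column names are
configurable through :class:`~actmotifs.types.ColumnSchema`. Timestamps are
treated as local wall-clock instants (the 5 AM day split is a wall-clock
rule); no timezone conversion is performed.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

from .types import (ACTIVITY_COLUMN, ACTIVITY_TYPES, CHECKIN_COLUMNS,
                    ColumnSchema, ConfigError, DailySequence, length_histogram)

log = logging.getLogger(__name__)

__all__ = [
    "CheckinFormatError",
    "CategoryMap",
    "read_checkins",
    "write_checkins",
    "load_category_map",
    "default_category_map",
    "assign_activity_types",
    "write_sequences",
    "read_sequences",
    "write_sequence_summary",
]


class CheckinFormatError(ValueError):
    """Raised in strict mode when rows fail to parse; carries row numbers."""

    def __init__(self, message: str, rows: list[int]):
        super().__init__(message)
        self.rows = rows


def read_checkins(path, schema: ColumnSchema | None = None,
                  delimiter: str = ",", strict: bool = True) -> pd.DataFrame:
    """Read a raw check-in table into a DataFrame with internal column names.

    Row order is preserved. Malformed rows (unparseable timestamp, lat/lon
    out of range) are reported with 1-based file line numbers: in strict mode
    the run fails; otherwise they are dropped with a warning.
    """
    schema = schema or ColumnSchema()
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    missing = [c for c in schema.required() if c not in df.columns]
    if missing:
        raise ConfigError(f"missing column(s) {missing} in {path}")
    out = pd.DataFrame({
        "user_id": df[schema.user_id],
        "poi_id": df[schema.poi_id],
        "lat": pd.to_numeric(df[schema.lat], errors="coerce"),
        "lon": pd.to_numeric(df[schema.lon], errors="coerce"),
        "timestamp": pd.to_datetime(df[schema.timestamp], errors="coerce",
                                    format="mixed"),
        "category_id": df[schema.category_id],
    })
    bad = (out["timestamp"].isna() | out["lat"].isna() | out["lon"].isna()
           | ~out["lat"].between(-90, 90) | ~out["lon"].between(-180, 180))
    if bad.any():
        # +2: one for the header line, one for 1-based numbering
        rows = [int(i) + 2 for i in out.index[bad]]
        if strict:
            raise CheckinFormatError(
                f"{len(rows)} malformed row(s) in {path} at file line(s) "
                f"{rows[:20]}", rows)
        log.warning("dropping %d malformed row(s) at file line(s) %s",
                    len(rows), rows[:20])
        out = out[~bad]
    return out.reset_index(drop=True)


def write_checkins(records: pd.DataFrame, path,
                   schema: ColumnSchema | None = None,
                   delimiter: str = ",") -> None:
    """Write records in the interchange format (round-trips with
    :func:`read_checkins` on all fields)."""
    schema = schema or ColumnSchema()
    cols = list(CHECKIN_COLUMNS)
    if ACTIVITY_COLUMN in records.columns:
        cols.append(ACTIVITY_COLUMN)
    out = records[cols].copy()
    out["timestamp"] = out["timestamp"].dt.strftime("%Y-%m-%d %H:%M:%S")
    rename = dict(zip(CHECKIN_COLUMNS, (schema.user_id, schema.poi_id,
                                        schema.lat, schema.lon,
                                        schema.timestamp, schema.category_id)))
    out.rename(columns=rename).to_csv(path, sep=delimiter, index=False)


@dataclass(frozen=True)
class CategoryMap:
    """Mapping from POI category identifiers to the seven activity types.

    ``default_policy`` governs unmapped categories: ``"error"`` aborts,
    ``"drop"`` removes the records, any activity-type name acts as a
    fallback type.
    """

    entries: dict[str, str]
    default_policy: str = "error"

    def __post_init__(self):
        bad = {c: t for c, t in self.entries.items()
               if t not in ACTIVITY_TYPES}
        if bad:
            raise ConfigError(f"category map targets outside the 7 activity "
                              f"types: {bad}")
        if (self.default_policy not in ("error", "drop")
                and self.default_policy not in ACTIVITY_TYPES):
            raise ConfigError(
                f"default_policy must be 'error', 'drop', or an activity "
                f"type, got {self.default_policy!r}")


def load_category_map(path, default_policy: str = "error",
                      delimiter: str = ",") -> CategoryMap:
    """Load a two-column ``category_id,activity_type`` delimited file."""
    df = pd.read_csv(path, sep=delimiter, dtype=str, comment="#")
    for col in ("category_id", "activity_type"):
        if col not in df.columns:
            raise ConfigError(f"category map {path} lacks column {col!r}")
    if df["category_id"].duplicated().any():
        dupes = sorted(df.loc[df["category_id"].duplicated(), "category_id"])
        raise ConfigError(f"category map has duplicate categories: {dupes}")
    return CategoryMap(entries=dict(zip(df["category_id"],
                                        df["activity_type"])),
                       default_policy=default_policy)


def default_category_map(default_policy: str = "error") -> CategoryMap:
    """The packaged default mapping (first-level Gowalla-style categories
    plus a few documented second-level refinements such as home→Residence).
    It is a documented approximation meant to be edited per deposit."""
    with resources.as_file(resources.files("actmotifs") / "data"
                           / "default_category_map.csv") as p:
        return load_category_map(p, default_policy=default_policy)


def assign_activity_types(records: pd.DataFrame,
                          category_map: CategoryMap) -> pd.DataFrame:
    """Set ``activity_type`` on every record from its category.

    Pure per-record function (output independent of record order). Unmapped
    categories are handled per the map's ``default_policy``; drop counts are
    logged.
    """
    mapped = records["category_id"].map(category_map.entries)
    unmapped = mapped.isna()
    out = records.copy()
    out[ACTIVITY_COLUMN] = mapped
    if unmapped.any():
        offending = sorted(set(records.loc[unmapped, "category_id"]))
        if category_map.default_policy == "error":
            raise ConfigError(
                f"{int(unmapped.sum())} record(s) with unmapped categories: "
                f"{offending[:20]}")
        if category_map.default_policy == "drop":
            log.info("type assignment dropped %d record(s) with unmapped "
                     "categories %s", int(unmapped.sum()), offending[:20])
            return out[~unmapped].reset_index(drop=True)
        out.loc[unmapped, ACTIVITY_COLUMN] = category_map.default_policy
        log.info("type assignment defaulted %d record(s) to %s",
                 int(unmapped.sum()), category_map.default_policy)
    return out


def write_sequences(sequences: list[DailySequence], path) -> None:
    """Sequence store: one row per sequence with comma-joined type codes."""
    rows = [{
        "user_id": s.user_id,
        "day_anchor": s.day_anchor.isoformat(),
        "types": ",".join(s.types),
        "length": s.length,
    } for s in sequences]
    pd.DataFrame(rows, columns=["user_id", "day_anchor", "types",
                                "length"]).to_csv(path, sep="\t", index=False)


def read_sequences(path) -> list[DailySequence]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    out = []
    for _, row in df.iterrows():
        out.append(DailySequence(
            user_id=row["user_id"],
            day_anchor=pd.Timestamp(row["day_anchor"]).date(),
            types=tuple(row["types"].split(",")),
        ))
    return out


def write_occurrence_table(table, path, catalog=None) -> None:
    """Occurrence-table export: one row per observed pattern with its
    topology classification and flags; totals go to a ``.meta.json``
    sidecar so the table round-trips."""
    from .mining import OccurrenceTable  # local: avoid import cycle
    from .patterns import default_catalog, has_recurrence, is_sequential
    from .types import pattern_str

    catalog = catalog or default_catalog()
    rows = [{
        "pattern": pattern_str(p),
        "topology": catalog.classify(p),
        "n_edges": len(p),
        "n_nodes": len({x for e in p for x in e}),
        "sequential": is_sequential(p),
        "recurrence": has_recurrence(p),
        "count": c,
    } for p, c in sorted(table.counts.items())]
    pd.DataFrame(rows, columns=["pattern", "topology", "n_edges", "n_nodes",
                                "sequential", "recurrence", "count"]
                 ).to_csv(path, index=False)
    meta = {
        "n_sequences_total": table.n_sequences_total,
        "n_sequences_by_min_length": {str(k): v for k, v in
                                      table.n_sequences_by_min_length.items()},
    }
    _meta_path(path).write_text(json.dumps(meta, indent=2) + "\n")


def read_occurrence_table(path):
    from .mining import OccurrenceTable
    from .types import parse_pattern

    df = pd.read_csv(path)
    meta = json.loads(_meta_path(path).read_text())
    return OccurrenceTable(
        counts={parse_pattern(r): int(c)
                for r, c in zip(df["pattern"], df["count"])},
        n_sequences_total=int(meta["n_sequences_total"]),
        n_sequences_by_min_length={int(k): v for k, v in
                                   meta["n_sequences_by_min_length"].items()},
    )


def _meta_path(path) -> Path:
    p = Path(path)
    return p.with_suffix(p.suffix + ".meta.json")


def write_motifs(motif_set, path) -> None:
    """Motif-set export: pattern, topology, count, class threshold applied."""
    from .types import pattern_str

    rows = [{
        "pattern": pattern_str(p),
        "topology": motif_set.catalog.classify(p),
        "count": c,
        "threshold": motif_set.thresholds.for_pattern(p),
    } for p, c in motif_set.motifs.items()]
    pd.DataFrame(rows, columns=["pattern", "topology", "count", "threshold"]
                 ).to_csv(path, index=False)


def read_motif_patterns(path) -> list:
    from .types import parse_pattern

    df = pd.read_csv(path)
    return [parse_pattern(r) for r in df["pattern"]]


def write_sequence_summary(sequences: list[DailySequence], path,
                           extra: dict | None = None) -> None:
    summary = {
        "n_sequences": len(sequences),
        "n_users": len({s.user_id for s in sequences}),
        "length_histogram": {str(k): v for k, v in
                             length_histogram(sequences).items()},
    }
    if extra:
        summary.update(extra)
    Path(path).write_text(json.dumps(summary, indent=2) + "\n")
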