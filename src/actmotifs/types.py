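"""Core domain types: activity types, check-in schema, daily sequences, patterns.

The analysis works over seven activity types abstracted from POI categories.
Each type has a stable one-letter code used in pattern strings and table
exports; the canonical ordering below fixes row/column order everywhere.
"""
from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence, Tuple

#: Canonical activity types in export order.
ACTIVITY_TYPES: tuple[str, ...] = (
    "Residence",
    "Community",
    "Entertainment",
    "Food",
    "Outdoors",
    "Shopping",
    "Travel",
)

#: One-letter codes, same order as :data:`ACTIVITY_TYPES`.
TYPE_CODES: tuple[str, ...] = ("R", "C", "E", "F", "O", "S", "T")

CODE_OF: dict[str, str] = dict(zip(ACTIVITY_TYPES, TYPE_CODES))
NAME_OF: dict[str, str] = dict(zip(TYPE_CODES, ACTIVITY_TYPES))

N_TYPES = len(ACTIVITY_TYPES)

#: A typed transition: (source type code, destination type code).
Edge = Tuple[str, str]
#: A typed temporal pattern: edges in temporal order. Types ARE node identity,
#: so equality of edge lists is pattern equality — no relabeling freedom.
Pattern = Tuple[Edge, ...]


class ConfigError(ValueError):
    """Raised for invalid configuration (bad schema, thresholds, kernels...)."""


def as_code(type_or_code: str) -> str:
    """Normalize a full type name or one-letter code to the code."""
    if type_or_code in NAME_OF:
        return type_or_code
    try:
        return CODE_OF[type_or_code]
    except KeyError:
        raise ConfigError(f"unknown activity type {type_or_code!r}") from None


def parse_pattern(text: str) -> Pattern:
    """Parse a pattern string like ``"F>S,S>E"`` into a :data:`Pattern`.

    One-letter codes, ``>`` for the transition, ``,`` between temporally
    ordered edges.
    """
    edges = []
    for part in text.split(","):
        part = part.strip()
        try:
            src, dst = part.split(">")
        except ValueError:
            raise ConfigError(f"malformed pattern edge {part!r}") from None
        edges.append((as_code(src.strip()), as_code(dst.strip())))
    return tuple(edges)


def pattern_str(pattern: Pattern) -> str:
    """Inverse of :func:`parse_pattern`."""
    return ",".join(f"{a}>{b}" for a, b in pattern)


@dataclass(frozen=True)
class ColumnSchema:
    """Column names of a raw check-in table.

    The defaults match the documented interchange format; point the fields at
    a deposit's actual header instead of renaming columns upstream.
    """

    user_id: str = "user_id"
    poi_id: str = "poi_id"
    lat: str = "lat"
    lon: str = "lon"
    timestamp: str = "datetime"
    category_id: str = "category_id"

    def required(self) -> tuple[str, ...]:
        return (self.user_id, self.poi_id, self.lat, self.lon,
                self.timestamp, self.category_id)


#: Internal (post-read) column names for check-in DataFrames.
CHECKIN_COLUMNS = ("user_id", "poi_id", "lat", "lon", "timestamp",
                   "category_id")
ACTIVITY_COLUMN = "activity_type"


@dataclass(frozen=True)
class DailySequence:
    """One user's merged activity-type sequence for one 5 AM-anchored day.

    ``types`` holds one-letter codes with adjacent runs already merged;
    ``times`` (optional) holds the first timestamp of each merged run.
    """

    user_id: str
    day_anchor: _dt.date
    types: tuple[str, ...]
    times: tuple[_dt.datetime, ...] | None = None

    def __post_init__(self) -> None:
        for a, b in zip(self.types, self.types[1:]):
            if a == b:
                raise ValueError("adjacent equal types: runs not merged")

    @property
    def length(self) -> int:
        return len(self.types)

    @property
    def n_transitions(self) -> int:
        return len(self.types) - 1

    def transitions(self) -> Pattern:
        """The day's ordered transition list as typed edges."""
        return tuple(zip(self.types, self.types[1:]))


def length_histogram(sequences: Iterable[DailySequence]) -> dict[int, int]:
    hist: dict[int, int] = {}
    for s in sequences:
        hist[s.length] = hist.get(s.length, 0) + 1
    return dict(sorted(hist.items()))
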