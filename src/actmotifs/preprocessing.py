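"""Cleaning check-ins and building merged daily activity-type sequences.

Pipeline order mirrors the data-cleaning description: drop low-activity POIs
(counts taken on the raw input, single pass), drop check-ins closer than a
minimum gap to the last *kept* check-in of the same user (greedy keep-first),
segment by a 5:00 AM wall-clock day boundary, then merge consecutive runs of
the same activity type and keep days with at least two merged items.
"""
from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .types import (ACTIVITY_COLUMN, CODE_OF, ConfigError, DailySequence,
                    length_histogram)

log = logging.getLogger(__name__)

__all__ = [
    "filter_low_activity_pois",
    "filter_short_intervals",
    "segment_days",
    "build_daily_sequences",
    "preprocess",
    "SequenceStats",
]

DAY_ANCHOR_COLUMN = "day_anchor"


def filter_low_activity_pois(records: pd.DataFrame,
                             min_count: int = 10) -> pd.DataFrame:
    """Keep only records whose POI has at least ``min_count`` check-ins in
    the *input* collection (single pass; no re-iteration after removal)."""
    if min_count < 1:
        raise ConfigError("min_count must be >= 1")
    counts = records["poi_id"].value_counts()
    keep = records["poi_id"].map(counts) >= min_count
    out = records[keep].copy()
    log.info("POI filter (min %d check-ins): %d -> %d records",
             min_count, len(records), len(out))
    return out


def filter_short_intervals(records: pd.DataFrame,
                           min_gap: _dt.timedelta = _dt.timedelta(minutes=10)
                           ) -> pd.DataFrame:
    """Per user, scan check-ins in time order (stable on input order for tied
    timestamps) and keep a record iff it is at least ``min_gap`` after the
    last KEPT record of that user. The first record per user is always kept.
    """
    if len(records) == 0:
        return records.copy()
    gap = pd.Timedelta(min_gap)
    order = records.assign(_row=np.arange(len(records)))
    order = order.sort_values(["user_id", "timestamp", "_row"], kind="stable")
    keep_rows: list[int] = []
    for _, grp in order.groupby("user_id", sort=False):
        last_kept = None
        for row, ts in zip(grp["_row"], grp["timestamp"]):
            if last_kept is None or ts - last_kept >= gap:
                keep_rows.append(row)
                last_kept = ts
    keep_rows = sorted(keep_rows)
    out = records.iloc[keep_rows].copy()
    log.info("interval filter (min gap %s): %d -> %d records",
             gap, len(records), len(out))
    return out


def segment_days(records: pd.DataFrame, boundary_hour: int = 5) -> pd.DataFrame:
    """Assign each record to the wall-clock day window starting at the most
    recent ``boundary_hour``:00 at or before it (half-open, 24 h long).
    Adds a ``day_anchor`` date column."""
    if not 0 <= boundary_hour <= 23:
        raise ConfigError("boundary_hour must be in 0..23")
    out = records.copy()
    shifted = out["timestamp"] - pd.Timedelta(hours=boundary_hour)
    out[DAY_ANCHOR_COLUMN] = shifted.dt.date
    return out


@dataclass(frozen=True)
class SequenceStats:
    """Bookkeeping mirroring the pipeline's reported totals."""

    n_day_groups: int
    n_sequences: int
    n_users: int
    length_histogram: dict[int, int]

    def n_with_min_length(self, min_length: int) -> int:
        return sum(c for length, c in self.length_histogram.items()
                   if length >= min_length)

    def to_dict(self) -> dict:
        return asdict(self)


def build_daily_sequences(records: pd.DataFrame,
                          min_length: int = 2
                          ) -> tuple[list[DailySequence], SequenceStats]:
    """Collapse each (user, day window) group into a run-merged activity
    sequence; a merged run is stamped with its first timestamp and days
    shorter than ``min_length`` merged items are excluded.

    Records must already carry ``activity_type`` and ``day_anchor``.
    """
    if ACTIVITY_COLUMN not in records.columns:
        raise ConfigError("records lack activity_type; assign types first")
    if DAY_ANCHOR_COLUMN not in records.columns:
        raise ConfigError("records lack day_anchor; run segment_days first")
    df = records.assign(_row=np.arange(len(records)))
    df = df.sort_values(["user_id", DAY_ANCHOR_COLUMN, "timestamp", "_row"],
                        kind="stable")
    sequences: list[DailySequence] = []
    n_groups = 0
    for (user, anchor), grp in df.groupby(["user_id", DAY_ANCHOR_COLUMN],
                                          sort=True):
        n_groups += 1
        types: list[str] = []
        times: list[_dt.datetime] = []
        for code, ts in zip(grp[ACTIVITY_COLUMN].map(CODE_OF).fillna(
                grp[ACTIVITY_COLUMN]), grp["timestamp"]):
            if not types or types[-1] != code:
                types.append(code)
                times.append(ts.to_pydatetime() if hasattr(ts, "to_pydatetime")
                             else ts)
        if len(types) >= min_length:
            sequences.append(DailySequence(user_id=str(user), day_anchor=anchor,
                                           types=tuple(types),
                                           times=tuple(times)))
    stats = SequenceStats(
        n_day_groups=n_groups,
        n_sequences=len(sequences),
        n_users=len({s.user_id for s in sequences}),
        length_histogram=length_histogram(sequences),
    )
    log.info("daily sequences: %d day groups -> %d sequences (length >= %d) "
             "from %d users", n_groups, stats.n_sequences, min_length,
             stats.n_users)
    return sequences, stats


def preprocess(records: pd.DataFrame,
               min_poi_checkins: int = 10,
               min_interval: _dt.timedelta = _dt.timedelta(minutes=10),
               boundary_hour: int = 5
               ) -> tuple[list[DailySequence], SequenceStats]:
    """Full cleaning pipeline on typed records: POI filter, interval filter,
    day segmentation, run-merged sequence construction."""
    step = filter_low_activity_pois(records, min_poi_checkins)
    step = filter_short_intervals(step, min_interval)
    step = segment_days(step, boundary_hour)
    return build_daily_sequences(step)
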