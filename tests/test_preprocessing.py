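"""Cleaning filters, day segmentation, and run-merged sequence building."""
import datetime as dt

import pandas as pd
import pytest

from actmotifs.preprocessing import (build_daily_sequences,
                                     filter_low_activity_pois,
                                     filter_short_intervals, preprocess,
                                     segment_days)
from actmotifs.types import ConfigError
from conftest import mkrecords


class TestPoiFilter:
    def test_poi_below_threshold_fully_removed(self):
        df = mkrecords([("u1", "p1", f"09:{m:02d}", "food")
                        for m in range(9)])
        assert len(filter_low_activity_pois(df, 10)) == 0

    def test_poi_at_threshold_kept(self):
        df = mkrecords([("u1", "p1", f"09:{m:02d}", "food")
                        for m in range(10)])
        assert len(filter_low_activity_pois(df, 10)) == 10

    def test_mixed_pois_counts_on_input(self):
        rows = ([("u1", "small", f"09:{m:02d}", "food") for m in range(5)]
                + [("u1", "mid", f"10:{m:02d}", "food") for m in range(10)]
                + [("u1", "big", f"{11 + m // 60}:{m % 60:02d}", "food")
                   for m in range(50)])
        out = filter_low_activity_pois(mkrecords(rows), 10)
        assert len(out) == 60
        assert set(out["poi_id"]) == {"mid", "big"}

    def test_min_count_below_one_rejected(self):
        with pytest.raises(ConfigError):
            filter_low_activity_pois(mkrecords([("u1", "p1", "09:00",
                                                 "food")]), 0)


class TestIntervalFilter:
    def test_greedy_keeps_record_ten_minutes_after_last_kept(self):
        # gaps [5m, 5m]: t0 kept, t0+5 dropped, t0+10 is 10m after t0 -> kept
        df = mkrecords([("u1", "p1", "09:00", "food"),
                        ("u1", "p1", "09:05", "food"),
                        ("u1", "p1", "09:10", "food")])
        out = filter_short_intervals(df)
        assert [ts.minute for ts in out["timestamp"]] == [0, 10]

    def test_all_gaps_at_least_ten_minutes_identity(self):
        df = mkrecords([("u1", "p1", "09:00", "food"),
                        ("u1", "p1", "09:10", "food"),
                        ("u1", "p1", "09:25", "food")])
        pd.testing.assert_frame_equal(filter_short_intervals(df), df)

    def test_users_filtered_independently(self):
        df = mkrecords([("u1", "p1", "09:00", "food"),
                        ("u2", "p1", "09:02", "food"),
                        ("u1", "p1", "09:04", "food"),
                        ("u2", "p1", "09:06", "food")])
        out = filter_short_intervals(df)
        # each user keeps only their own first record; interleaving invisible
        assert list(out["user_id"]) == ["u1", "u2"]
        assert [ts.minute for ts in out["timestamp"]] == [0, 2]

    def test_permuting_other_users_rows_is_invisible(self):
        rows = [("u1", "p1", "09:00", "food"), ("u1", "p1", "09:04", "food"),
                ("u2", "p2", "08:00", "food"), ("u2", "p2", "09:30", "food")]
        base = filter_short_intervals(mkrecords(rows))
        shuffled = filter_short_intervals(
            mkrecords([rows[2], rows[0], rows[3], rows[1]]))
        for user in ("u1", "u2"):
            assert list(base.loc[base.user_id == user, "timestamp"]) == \
                list(shuffled.loc[shuffled.user_id == user, "timestamp"])


class TestSegmentDays:
    def test_before_boundary_belongs_to_previous_day(self):
        df = mkrecords([("u1", "p1", dt.datetime(2010, 3, 2, 4, 59), "food")])
        out = segment_days(df)
        assert out["day_anchor"].iloc[0] == dt.date(2010, 3, 1)

    def test_at_boundary_belongs_to_that_day(self):
        df = mkrecords([("u1", "p1", dt.datetime(2010, 3, 2, 5, 0), "food")])
        out = segment_days(df)
        assert out["day_anchor"].iloc[0] == dt.date(2010, 3, 2)

    def test_evening_and_small_hours_share_a_window(self):
        df = mkrecords([("u1", "p1", dt.datetime(2010, 3, 1, 23, 0), "food"),
                        ("u1", "p2", dt.datetime(2010, 3, 2, 2, 0),
                         "shopping")])
        out = segment_days(df)
        assert out["day_anchor"].nunique() == 1

    def test_boundary_hour_validated(self):
        with pytest.raises(ConfigError):
            segment_days(mkrecords([("u1", "p1", "09:00", "food")]),
                         boundary_hour=24)


class TestBuildDailySequences:
    def mk(self, typed_rows):
        df = mkrecords(typed_rows)
        return segment_days(df)

    def test_adjacent_identical_types_merge(self):
        seqs, _ = build_daily_sequences(self.mk(
            [("u1", "p1", "09:00", "food", "Food"),
             ("u1", "p1", "10:00", "food", "Food"),
             ("u1", "p2", "11:00", "shopping", "Shopping")]))
        assert len(seqs) == 1
        assert seqs[0].types == ("F", "S")
        assert seqs[0].times[0].hour == 9  # first timestamp of the run

    def test_single_type_day_excluded(self):
        seqs, stats = build_daily_sequences(self.mk(
            [("u1", "p1", f"{9 + h}:00", "food", "Food") for h in range(3)]))
        assert seqs == []
        assert stats.n_day_groups == 1

    def test_worked_five_item_day(self):
        seqs, _ = build_daily_sequences(self.mk(
            [("u1", "p1", "08:00", "c", "Residence"),
             ("u1", "p2", "10:00", "c", "Community"),
             ("u1", "p3", "12:00", "c", "Outdoors"),
             ("u1", "p4", "15:00", "c", "Community"),
             ("u1", "p5", "19:00", "c", "Residence")]))
        assert seqs[0].types == ("R", "C", "O", "C", "R")
        assert seqs[0].n_transitions == 4

    def test_merge_is_idempotent_and_no_adjacent_equals(self):
        seqs, _ = build_daily_sequences(self.mk(
            [("u1", "p1", f"09:{m:02d}", "c", t) for m, t in
             zip(range(0, 60, 7), ["Food", "Food", "Food", "Shopping",
                                   "Shopping", "Food", "Food", "Travel"])]))
        types = seqs[0].types
        assert types == ("F", "S", "F", "T")
        assert all(a != b for a, b in zip(types, types[1:]))

    def test_length_bookkeeping(self):
        seqs, stats = build_daily_sequences(self.mk(
            [("u1", "p1", "09:00", "c", "Food"),
             ("u1", "p2", "10:00", "c", "Shopping"),
             ("u2", "p1", "09:00", "c", "Food"),
             ("u2", "p2", "10:00", "c", "Travel"),
             ("u2", "p3", "11:00", "c", "Food")]))
        assert stats.length_histogram == {2: 1, 3: 1}
        assert all(s.n_transitions == s.length - 1 for s in seqs)


def test_pipeline_deterministic_under_row_permutation():
    types = ["Food", "Shopping", "Food", "Travel", "Outdoors"] * 2
    rows = [("u1", "p1", f"{8 + i}:00", "c", t)
            for i, t in enumerate(types)]
    rows += [("u2", "p1", f"{8 + i}:30", "c", t)
             for i, t in enumerate(reversed(types))]
    base = mkrecords(rows)
    shuffled = base.sample(frac=1, random_state=4).reset_index(drop=True)
    s1, _ = preprocess(base, min_poi_checkins=10)
    s2, _ = preprocess(shuffled, min_poi_checkins=10)
    key = lambda s: (s.user_id, s.day_anchor)
    assert sorted([(key(s), s.types) for s in s1]) == \
        sorted([(key(s), s.types) for s in s2])
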