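import datetime as dt

import pandas as pd
import pytest

from actmotifs.types import DailySequence


def mkseq(codes: str, user: str = "u1",
          anchor: dt.date = dt.date(2010, 3, 1)) -> DailySequence:
    """Build a merged daily sequence from a code string like 'RCOCR'."""
    return DailySequence(user_id=user, day_anchor=anchor, types=tuple(codes))


def mkrecords(rows):
    """Build an internal-format check-in frame from
    (user, poi, hh:mm-or-datetime, category[, activity]) tuples."""
    base = dt.datetime(2010, 3, 1)
    out = []
    has_activity = len(rows[0]) > 4
    for row in rows:
        user, poi, when, category = row[:4]
        if isinstance(when, str):
            h, m = map(int, when.split(":"))
            when = base.replace(hour=h, minute=m)
        rec = {"user_id": user, "poi_id": poi, "lat": 40.7, "lon": -74.0,
               "timestamp": pd.Timestamp(when), "category_id": category}
        if has_activity:
            rec["activity_type"] = row[4]
        out.append(rec)
    return pd.DataFrame(out)


@pytest.fixture
def seq_factory():
    return mkseq


@pytest.fixture
def record_factory():
    return mkrecords
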