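"""Synthetic check-in corpora with controllable statistical structure.

Each user-day is simulated as a first-order Markov chain over the seven
activity types: an initial type drawn from the marginal vector, subsequent
types from a row-stochastic transition kernel. The kernel keeps some mass on
the diagonal so raw streams contain runs of repeated types that the
run-merging step collapses, as real check-in streams do. Daily check-in
counts are geometric (most days one or two check-ins, a minority of four or
more), and only a fraction of user-days are active, giving the heavy-tailed,
imbalanced daily-length distribution the pipeline expects. Timestamps are
distinct minutes spread over the 5 AM-anchored day; each record gets a POI
from a per-type pool (popular POIs plus a sparse tail that the min-check-in
filter removes) and a category id resolvable by the default category map.

Planted patterns boost chosen kernel entries multiplicatively (with row
renormalization) so that specific motifs can be pushed above or held below
the selection thresholds in tests.
"""
from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import (ACTIVITY_TYPES, CODE_OF, ConfigError, DailySequence,
                    N_TYPES, Pattern, parse_pattern)

__all__ = [
    "SimulationConfig",
    "default_marginals",
    "default_kernel",
    "generate_checkins",
    "make_fixture_corpus",
    "fixture_checkins",
    "FIXTURE_NAMES",
]

#: Type marginals used by default (order: R, C, E, F, O, S, T). Roughly
#: check-in-like: Community/Food heavy, Residence and Shopping light.
_DEFAULT_MARGINALS = (0.10, 0.20, 0.15, 0.20, 0.15, 0.08, 0.12)

#: Mass kept on the diagonal so raw streams contain mergeable runs.
_SELF_TRANSITION = 0.15

#: Categories emitted per type, resolvable by the packaged default map.
_CATEGORY_OF = {
    "Residence": "community:home",
    "Community": "community",
    "Entertainment": "nightlife",
    "Food": "food",
    "Outdoors": "outdoors",
    "Shopping": "shopping",
    "Travel": "travel",
}


def default_marginals() -> np.ndarray:
    return np.array(_DEFAULT_MARGINALS)


def default_kernel(marginals: np.ndarray | None = None,
                   self_transition: float = _SELF_TRANSITION) -> np.ndarray:
    """Row-stochastic kernel: ``self_transition`` on the diagonal, the rest
    proportional to the destination marginals."""
    m = default_marginals() if marginals is None else np.asarray(marginals)
    kernel = np.empty((N_TYPES, N_TYPES))
    for i in range(N_TYPES):
        off = m.copy()
        off[i] = 0.0
        kernel[i] = (1.0 - self_transition) * off / off.sum()
        kernel[i, i] = self_transition
    return kernel


@dataclass
class SimulationConfig:
    """Knobs of the generator; the seed fully determines the output."""

    n_users: int = 100
    days: int = 10
    seed: int = 0
    type_marginals: np.ndarray = field(default_factory=default_marginals)
    transition_kernel: np.ndarray = field(default_factory=default_kernel)
    #: (typed edge list, boost factor >= 1) pairs applied by renormalization
    planted_patterns: list[tuple[Pattern, float]] = field(default_factory=list)
    #: geometric parameter of the daily check-in count (support 1, 2, ...)
    length_p: float = 0.45
    #: probability that a user-day has any check-ins at all
    p_active_day: float = 0.65
    boundary_hour: int = 5
    start_date: _dt.date = _dt.date(2010, 3, 1)
    #: popular POIs per activity type (reused heavily, survive the filter)
    pois_per_type: int = 15
    #: fraction of check-ins sent to fresh single-use POIs instead
    sparse_poi_fraction: float = 0.04

    def effective_kernel(self) -> np.ndarray:
        kernel = np.array(self.transition_kernel, dtype=float)
        if kernel.shape != (N_TYPES, N_TYPES):
            raise ConfigError(f"kernel must be {N_TYPES}x{N_TYPES}")
        if (kernel < 0).any():
            raise ConfigError("kernel entries must be non-negative")
        if not np.allclose(kernel.sum(axis=1), 1.0, atol=1e-9):
            raise ConfigError("kernel rows must sum to 1")
        for pattern, boost in self.planted_patterns:
            if boost < 1:
                raise ConfigError("boost factors must be >= 1")
            edges = parse_pattern(pattern) if isinstance(pattern, str) else pattern
            for src, dst in edges:
                i = _CODE_INDEX[src]
                j = _CODE_INDEX[dst]
                kernel[i, j] *= boost
        kernel /= kernel.sum(axis=1, keepdims=True)
        return kernel


_CODE_INDEX = {CODE_OF[name]: i for i, name in enumerate(ACTIVITY_TYPES)}


def generate_checkins(config: SimulationConfig) -> pd.DataFrame:
    """Simulate a raw check-in table (interchange columns, untyped).

    Byte-identical output for equal configs: one ``numpy`` generator seeded
    from ``config.seed`` drives every draw in a fixed order.
    """
    rng = np.random.default_rng(config.seed)
    kernel = config.effective_kernel()
    marginals = np.asarray(config.type_marginals, dtype=float)
    if not np.isclose(marginals.sum(), 1.0, atol=1e-9):
        raise ConfigError("type marginals must sum to 1")
    kernel_cum = kernel.cumsum(axis=1)
    marg_cum = marginals.cumsum()

    poi_names = [[f"{CODE_OF[t]}{i:03d}" for i in range(config.pois_per_type)]
                 for t in ACTIVITY_TYPES]
    # fixed metro-like POI coordinates per popular POI
    poi_coords = rng.uniform((40.4, -74.3), (41.0, -73.7),
                             size=(N_TYPES, config.pois_per_type, 2))
    sparse_serial = 0

    rows: list[tuple] = []
    day_minutes = 24 * 60
    for u in range(config.n_users):
        user = f"u{u:05d}"
        for d in range(config.days):
            if rng.random() >= config.p_active_day:
                continue
            n = int(rng.geometric(config.length_p))
            anchor = config.start_date + _dt.timedelta(days=d)
            t0 = _dt.datetime.combine(anchor, _dt.time(config.boundary_hour))
            minutes = np.sort(rng.choice(day_minutes, size=min(n, day_minutes),
                                         replace=False))
            state = int(np.searchsorted(marg_cum, rng.random()))
            for minute in minutes:
                t_name = ACTIVITY_TYPES[state]
                if rng.random() < config.sparse_poi_fraction:
                    sparse_serial += 1
                    poi = f"{CODE_OF[t_name]}rare{sparse_serial:05d}"
                    lat, lon = rng.uniform((40.4, -74.3), (41.0, -73.7))
                else:
                    j = int(rng.integers(config.pois_per_type))
                    poi = poi_names[state][j]
                    lat, lon = poi_coords[state, j]
                rows.append((user, poi, round(float(lat), 6),
                             round(float(lon), 6),
                             t0 + _dt.timedelta(minutes=int(minute)),
                             _CATEGORY_OF[t_name]))
                state = int(np.searchsorted(kernel_cum[state], rng.random()))
    return pd.DataFrame(rows, columns=["user_id", "poi_id", "lat", "lon",
                                       "timestamp", "category_id"])


# --- hand-written fixtures ------------------------------------------------

FIXTURE_NAMES = ("ring_day", "two_process_day")

_FIXTURES = {
    # a day visiting Residence, Community, Outdoors, Community, Residence:
    # contains the R>C,C>R ring once intermediate activities are skipped
    "ring_day": [("u1", "RCOCR")],
    # R>C early, F>E late, nothing linking them: the two-process candidate
    "two_process_day": [("u1", "RCSFE")],
}


def make_fixture_corpus(name: str) -> list[DailySequence]:
    """Small hand-written daily-sequence corpora with hand-verified
    candidate sets; see :data:`FIXTURE_NAMES`."""
    try:
        days = _FIXTURES[name]
    except KeyError:
        raise ConfigError(f"unknown fixture {name!r}; "
                          f"choose from {FIXTURE_NAMES}") from None
    return [DailySequence(user_id=user, day_anchor=_dt.date(2010, 3, 1),
                          types=tuple(codes)) for user, codes in days]


def fixture_checkins(name: str = "boundary") -> pd.DataFrame:
    """Hand-written raw check-in fixtures; ``"boundary"`` holds one user's
    records at 04:59 and 05:00 spanning the 5 AM day split."""
    if name != "boundary":
        raise ConfigError(f"unknown check-in fixture {name!r}")
    rows = [
        ("u1", "F000", 40.7, -74.0, _dt.datetime(2010, 3, 2, 4, 59), "food"),
        ("u1", "C000", 40.7, -74.0, _dt.datetime(2010, 3, 2, 5, 0),
         "community"),
    ]
    return pd.DataFrame(rows, columns=["user_id", "poi_id", "lat", "lon",
                                       "timestamp", "category_id"])
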