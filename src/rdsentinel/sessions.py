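"""Gap-rule sessionization of query logs around level-1 keyword matches.

A *session* is a maximal run of one user's queries in which consecutive
queries are separated by at most 30 minutes; a gap of exactly 30:00 does
not break a session (only a strictly greater interval does).  Only sessions
containing at least one *key query* — a query matching a level-1 RD keyword
— are retained (Session Set S).  Expanding backward/forward from each key
query and merging overlapping expansions is equivalent to keeping the
maximal gap-delimited block containing the key query; the implementation
uses the block form, and the test suite checks equivalence against a
literal backtrack/forward-trace oracle.
"""

from __future__ import annotations

import collections
import datetime as _dt
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .lexicon import Lexicon, QueryAnnotation

__all__ = [
    "DEFAULT_GAP_SECONDS",
    "LogRecord",
    "Session",
    "StudyWindow",
    "UserSessionStats",
    "build_sessions",
    "session_period",
    "user_session_stats",
]

DEFAULT_GAP_SECONDS = 30 * 60


@dataclass(frozen=True)
class LogRecord:
    """One query event: who searched what, when, where, and what they clicked.

    ``clicks`` holds (url_domain, position) pairs with 1-based ranking
    positions.
    """

    user_id: str
    timestamp: float
    region_id: int
    tokens: tuple[str, ...]
    clicks: tuple[tuple[str, int], ...] = ()

    def __post_init__(self) -> None:
        if self.timestamp < 0:
            raise ValueError("timestamps must be nonnegative")
        for _, pos in self.clicks:
            if pos < 1:
                raise ValueError("click positions are 1-based (>= 1)")


@dataclass
class Session:
    """A gap-delimited query sequence anchored by >=1 level-1 key query."""

    user_id: str
    record_ids: list[int]
    records: list[LogRecord]
    key_indices: list[int]
    annotations: list[QueryAnnotation] = field(default_factory=list)
    disease_ids: set[int] = field(default_factory=set)
    region_id: int | None = None
    period_id: int | None = None
    intent: str = "UNLABELED"

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class StudyWindow:
    """Calendar window mapping timestamps to season (quarter) indices 1..T."""

    start_year: int = 2016
    n_periods: int = 16

    def period_of(self, timestamp: float) -> int:
        dt = _dt.datetime.fromtimestamp(timestamp, tz=_dt.timezone.utc)
        period = (dt.year - self.start_year) * 4 + (dt.month - 1) // 3 + 1
        if not 1 <= period <= self.n_periods:
            raise ValueError(
                f"timestamp {dt.isoformat()} falls outside the study window "
                f"({self.start_year}Q1 .. period {self.n_periods})"
            )
        return period

    def period_bounds(self, period: int) -> tuple[float, float]:
        """UTC epoch-second bounds [start, end) of a 1-based period."""
        if not 1 <= period <= self.n_periods:
            raise ValueError(f"period {period} outside 1..{self.n_periods}")
        year, quarter = divmod(period - 1, 4)
        start = _dt.datetime(
            self.start_year + year, 3 * quarter + 1, 1, tzinfo=_dt.timezone.utc
        )
        if quarter == 3:
            end = _dt.datetime(self.start_year + year + 1, 1, 1, tzinfo=_dt.timezone.utc)
        else:
            end = _dt.datetime(
                self.start_year + year, 3 * quarter + 4, 1, tzinfo=_dt.timezone.utc
            )
        return start.timestamp(), end.timestamp()


def session_period(session: Session, window: StudyWindow) -> int:
    """Season index of a session: the quarter of its first key query."""
    if not session.records:
        raise ValueError("empty session")
    first_key = session.records[session.key_indices[0]]
    return window.period_of(first_key.timestamp)


def build_sessions(
    records: Sequence[LogRecord],
    key_ids: Iterable[int],
    lexicon: Lexicon | None = None,
    window: StudyWindow | None = None,
    gap_seconds: float = DEFAULT_GAP_SECONDS,
) -> list[Session]:
    """Build Session Set S from time-sorted logs and level-1 record ids.

    Parameters
    ----------
    records
        All log records; ids are positions in this sequence.  Records must
        be sorted by (user_id, timestamp); ties keep input order.
    key_ids
        Ids of records matching a level-1 keyword (e.g. from
        :func:`rdsentinel.lexicon.build_query_set`).
    lexicon
        When given, every record of every returned session is annotated and
        the session's ``disease_ids`` is the union of its key queries'
        level-1 disease hits.
    window
        When given, sessions get a ``period_id`` (quarter of the first key
        query).

    Sessions that would arise from distinct key queries of the same user
    and share records are merged (each maximal block is emitted once).
    """
    key_ids = set(key_ids)
    n = len(records)
    for k in key_ids:
        if not 0 <= k < n:
            raise KeyError(f"key query id {k} not present in logs (0..{n - 1})")

    by_user: dict[str, list[int]] = collections.defaultdict(list)
    for i, rec in enumerate(records):
        by_user[rec.user_id].append(i)

    sessions: list[Session] = []
    for user in by_user:
        ids = by_user[user]
        if any(
            records[a].timestamp > records[b].timestamp
            for a, b in zip(ids, ids[1:])
        ):
            raise ValueError(f"records of user {user!r} are not time-sorted")
        block: list[int] = []
        for i in ids:
            if block and (
                records[i].timestamp - records[block[-1]].timestamp > gap_seconds
            ):
                _emit(sessions, user, block, key_ids, records, lexicon, window)
                block = []
            block.append(i)
        _emit(sessions, user, block, key_ids, records, lexicon, window)
    return sessions


def _emit(sessions, user, block, key_ids, records, lexicon, window) -> None:
    if not block:
        return
    key_indices = [j for j, i in enumerate(block) if i in key_ids]
    if not key_indices:
        return
    recs = [records[i] for i in block]
    session = Session(
        user_id=user,
        record_ids=list(block),
        records=recs,
        key_indices=key_indices,
        region_id=recs[key_indices[0]].region_id,
    )
    if lexicon is not None:
        session.annotations = [lexicon.match_query(r.tokens) for r in recs]
        session.disease_ids = set().union(
            *(session.annotations[j].level1_hits for j in key_indices)
        )
    if window is not None:
        session.period_id = session_period(session, window)
    sessions.append(session)


@dataclass(frozen=True)
class UserSessionStats:
    """Per-user repeat-search summary of a session set."""

    n_sessions: int
    n_users: int
    mean_sessions_per_user: float
    frac_single_session: float
    frac_lt4_sessions: float


def user_session_stats(sessions: Sequence[Session]) -> UserSessionStats:
    """Arithmetic over per-user session counts (repeat-search behaviour)."""
    if not sessions:
        raise ValueError("empty session set")
    counts = collections.Counter(s.user_id for s in sessions)
    n_users = len(counts)
    n_sessions = len(sessions)
    return UserSessionStats(
        n_sessions=n_sessions,
        n_users=n_users,
        mean_sessions_per_user=n_sessions / n_users,
        frac_single_session=sum(1 for c in counts.values() if c == 1) / n_users,
        frac_lt4_sessions=sum(1 for c in counts.values() if c < 4) / n_users,
    )
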