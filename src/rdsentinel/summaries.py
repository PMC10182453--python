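"""Arithmetic over corpus-level summary counts.

Small, exact computations used when only aggregate counts are available
(e.g. when auditing a published summary table): totals over query
categories, per-user session averages, and intent-class shares.
"""

from __future__ import annotations

from typing import Mapping, Sequence

__all__ = ["total_queries", "sessions_per_user", "intent_shares"]


def total_queries(category_counts: Mapping[str, int]) -> int:
    """|Q|: the category counts partition the query set."""
    if any(v < 0 for v in category_counts.values()):
        raise ValueError("counts must be nonnegative")
    return sum(category_counts.values())


def sessions_per_user(n_sessions: int, n_users: int) -> float:
    """Mean sessions per user from corpus totals."""
    if n_users <= 0:
        raise ValueError("need at least one user")
    return n_sessions / n_users


def intent_shares(counts: Sequence[int]) -> tuple[float, ...]:
    """Percentage share of each intent class among classified sessions."""
    total = sum(counts)
    if total <= 0:
        raise ValueError("no sessions")
    return tuple(100.0 * c / total for c in counts)
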