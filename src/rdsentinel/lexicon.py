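"""Three-level rare-disease keyword lexicon and query annotation.

The vocabulary is organized by how specifically a keyword points at a rare
disease (RD):

* **level 1** — RD-specific terms (disease names, causal genes, specific
  treatments); a query containing one is direct evidence of RD relevance.
* **level 2** — RD-related but non-specific terms (symptoms, pleiotropic
  treatments), each still tied to a particular disease.
* **level 3** — general medical vocabulary, tied to no disease.

Queries are annotated with the *highest-priority* level they match
(1 beats 2 beats 3), the set of diseases implicated by level-1/2 matches,
and — for level-1 matches — the keyword category (name / gene / treatment).

Matching is substring containment on the space-joined query text, which is
how keyword filters over commercial logs operate and keeps the module
independent of any tokenizer.
"""

from __future__ import annotations

import collections
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "LEVEL1_CATEGORIES",
    "LEVEL2_CATEGORIES",
    "KeywordEntry",
    "QueryAnnotation",
    "Lexicon",
    "QuerySet",
    "match_query",
    "build_query_set",
]

LEVEL1_CATEGORIES = ("name", "gene", "treatment")
LEVEL2_CATEGORIES = ("symptom", "pleiotropic_treatment")


@dataclass(frozen=True)
class KeywordEntry:
    """One lexicon entry: a keyword string, its level, and its provenance."""

    text: str
    level: int
    disease_id: int | None = None
    category: str | None = None

    def __post_init__(self) -> None:
        if not self.text:
            raise ValueError("keyword text must be non-empty")
        if self.level not in (1, 2, 3):
            raise ValueError(f"level must be 1, 2 or 3, got {self.level}")
        if self.level in (1, 2):
            if self.disease_id is None:
                raise ValueError(
                    f"level-{self.level} keyword {self.text!r} needs a disease_id"
                )
            if self.disease_id < 1:
                raise ValueError("disease_id must be >= 1")
            allowed = LEVEL1_CATEGORIES if self.level == 1 else LEVEL2_CATEGORIES
            if self.category not in allowed:
                raise ValueError(
                    f"level-{self.level} keyword {self.text!r}: category must be "
                    f"one of {allowed}, got {self.category!r}"
                )
        else:
            if self.disease_id is not None or self.category is not None:
                raise ValueError(
                    f"level-3 keyword {self.text!r} must not carry a disease or category"
                )


@dataclass(frozen=True)
class QueryAnnotation:
    """Result of matching one query against the lexicon.

    ``matched_level`` is the highest-priority matched level (1 > 2 > 3),
    or 0 when nothing matched.  ``disease_hits`` unions the diseases of all
    level-1 and level-2 matches; ``level1_hits`` restricts that to level-1
    matches (the session-level disease signal).  ``level1_category`` is set
    iff ``matched_level == 1``; when several level-1 categories match, the
    first in (name, gene, treatment) order wins.
    """

    matched_level: int
    disease_hits: frozenset[int] = frozenset()
    level1_hits: frozenset[int] = frozenset()
    level1_category: str | None = None

    def __post_init__(self) -> None:
        if (self.level1_category is not None) != (self.matched_level == 1):
            raise ValueError("level1_category present iff matched_level == 1")


class Lexicon:
    """Validated container of :class:`KeywordEntry` with query matching."""

    def __init__(self, entries: Iterable[KeywordEntry]):
        self.entries: tuple[KeywordEntry, ...] = tuple(entries)
        seen: set[tuple[int, str, int | None]] = set()
        for e in self.entries:
            key = (e.level, e.text, e.disease_id)
            if key in seen:
                raise ValueError(f"duplicate lexicon entry {key}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @property
    def disease_ids(self) -> tuple[int, ...]:
        return tuple(sorted({e.disease_id for e in self.entries if e.disease_id}))

    def match_query(self, tokens: Sequence[str]) -> QueryAnnotation:
        """Annotate one query (an ordered token list) against the lexicon.

        Containment means the keyword occurs as a contiguous substring of
        the space-joined query text.  An empty query matches nothing.
        """
        text = " ".join(tokens)
        if not text:
            return QueryAnnotation(matched_level=0)
        matched_level = 0
        disease_hits: set[int] = set()
        level1_hits: set[int] = set()
        level1_categories: set[str] = set()
        for e in self.entries:
            if e.text not in text:
                continue
            if matched_level == 0 or e.level < matched_level:
                matched_level = e.level
            if e.level in (1, 2):
                disease_hits.add(e.disease_id)
            if e.level == 1:
                level1_hits.add(e.disease_id)
                level1_categories.add(e.category)
        category = None
        if matched_level == 1:
            category = next(c for c in LEVEL1_CATEGORIES if c in level1_categories)
        return QueryAnnotation(
            matched_level=matched_level,
            disease_hits=frozenset(disease_hits),
            level1_hits=frozenset(level1_hits),
            level1_category=category,
        )

    # ---- serialization ---------------------------------------------------

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Lexicon":
        """Load a lexicon from a UTF-8 TSV of (text, level, disease_id, category).

        ``disease_id`` and ``category`` are empty strings for level-3 rows.
        """
        entries = []
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                text, level, disease_id, category = line.split("\t")
                entries.append(
                    KeywordEntry(
                        text=text,
                        level=int(level),
                        disease_id=int(disease_id) if disease_id else None,
                        category=category or None,
                    )
                )
        return cls(entries)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for e in self.entries:
                fh.write(
                    f"{e.text}\t{e.level}\t"
                    f"{'' if e.disease_id is None else e.disease_id}\t"
                    f"{e.category or ''}\n"
                )


def match_query(tokens: Sequence[str], lexicon: Lexicon) -> QueryAnnotation:
    """Functional alias for :meth:`Lexicon.match_query`."""
    return lexicon.match_query(tokens)


@dataclass(frozen=True)
class QuerySet:
    """The level-1-matched query set Q with per-category counts."""

    record_ids: frozenset[int]
    category_counts: dict = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.category_counts.values())

    def __len__(self) -> int:
        return len(self.record_ids)


def build_query_set(records, lexicon: Lexicon) -> QuerySet:
    """Select records whose query matches a level-1 keyword (Query Set Q).

    ``records`` is a sequence of objects with a ``tokens`` attribute; record
    ids are positions in the sequence.  The category counts (name / gene /
    treatment) partition Q.
    """
    ids = set()
    counts = collections.Counter()
    for i, rec in enumerate(records):
        ann = lexicon.match_query(rec.tokens)
        if ann.matched_level == 1:
            ids.add(i)
            counts[ann.level1_category] += 1
    counts = {c: counts.get(c, 0) for c in LEVEL1_CATEGORIES}
    return QuerySet(record_ids=frozenset(ids), category_counts=counts)
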