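"""Session and query feature extraction for intent prediction.

Each session is summarized by a 38-dimensional vector (8 statistical
features + 30 binary semantic indicators) and by a per-query sequence of
(6 + D)-dimensional vectors (6 statistical features + a D-dim disease
multi-hot; D = 15 diseases gives the 21-dim query vectors).

The *word-frequency-change* statistic is a burst indicator: for word ``w``
in period (season) ``t``,

    C(w, t) = (n(w, t) + alpha) / (sum_j n(w, j) / K + alpha)

with ``n`` the word's count in a period, ``K`` the number of periods and
``alpha = 1`` for smoothing.  Words that are equally common in every period
— and words never seen at all — score 1; breaking-news vocabulary spikes
above 1 in its burst season.

Semantic indicators come from a small vocabulary of intent-specific words
and clicked-URL domains: items frequent in one intent class and rare in the
other two (top 5 per class, for words and domains separately).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .intent_labels import INTENT_NAMES, as_intent_index
from .lexicon import QueryAnnotation
from .sessions import LogRecord, Session

__all__ = [
    "WordFrequencyModel",
    "SemanticVocabulary",
    "SessionFeatures",
    "word_freq_change",
    "query_features",
    "session_features",
    "select_semantic_vocabulary",
    "SessionFeaturizer",
    "N_SESSION_FEATURES",
]

#: session vector layout: 8 statistics then 30 semantic bits
N_SESSION_FEATURES = 38
_N_QUERY_STATS = 6


class WordFrequencyModel:
    """Per-period word counts with the smoothed change ratio C(w, t)."""

    def __init__(self, n_periods: int, alpha: float = 1.0):
        if n_periods < 1:
            raise ValueError("need at least one period")
        if alpha <= 0:
            raise ValueError("alpha must be positive")
        self.n_periods = n_periods
        self.alpha = alpha
        self.counts: dict[str, np.ndarray] = {}

    def add(self, word: str, period: int, count: int = 1) -> None:
        """Add ``count`` occurrences of ``word`` in 1-based ``period``."""
        if not 1 <= period <= self.n_periods:
            raise ValueError(f"period {period} outside 1..{self.n_periods}")
        arr = self.counts.get(word)
        if arr is None:
            arr = self.counts[word] = np.zeros(self.n_periods)
        arr[period - 1] += count

    @classmethod
    def fit(
        cls,
        sessions: Iterable[Session],
        n_periods: int,
        alpha: float = 1.0,
    ) -> "WordFrequencyModel":
        """Count token occurrences per season over all queries of a corpus."""
        model = cls(n_periods, alpha)
        for s in sessions:
            if s.period_id is None:
                raise ValueError("sessions must carry period_id to fit word counts")
            for rec in s.records:
                for tok in rec.tokens:
                    model.add(tok, s.period_id)
        return model

    def change(self, word: str, period: int) -> float:
        """C(w, t); an unknown word has n = 0 everywhere and scores 1."""
        if not 1 <= period <= self.n_periods:
            raise ValueError(f"period {period} outside 1..{self.n_periods}")
        arr = self.counts.get(word)
        if arr is None:
            return 1.0
        return float((arr[period - 1] + self.alpha) / (arr.mean() + self.alpha))

    def query_change(self, tokens: Sequence[str], period: int) -> float:
        """Query-level statistic: mean C over the query's words (1 if empty)."""
        if not tokens:
            return 1.0
        return float(np.mean([self.change(t, period) for t in tokens]))


def word_freq_change(model: WordFrequencyModel, word: str, period: int) -> float:
    """Functional alias for :meth:`WordFrequencyModel.change`."""
    return model.change(word, period)


@dataclass(frozen=True)
class SemanticVocabulary:
    """Intent-specific indicator vocabulary: 5 words and 5 URL domains per
    class, ordered RD, NEWS, OTHER (15 words + 15 domains = 30 bits)."""

    words: tuple[str, ...]
    url_domains: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.words)) != len(self.words):
            raise ValueError("duplicate words in semantic vocabulary")
        if len(set(self.url_domains)) != len(self.url_domains):
            raise ValueError("duplicate url domains in semantic vocabulary")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({"words": list(self.words), "url_domains": list(self.url_domains)})
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "SemanticVocabulary":
        d = json.loads(Path(path).read_text())
        return cls(words=tuple(d["words"]), url_domains=tuple(d["url_domains"]))


@dataclass
class SessionFeatures:
    """The 38-dim session vector plus the per-query feature sequence."""

    session_vector: np.ndarray
    query_sequence: np.ndarray  # shape (session_len, 6 + D)


# ---------------------------------------------------------------------------
# per-query features


def query_features(
    record: LogRecord,
    annotation: QueryAnnotation,
    wf_model: WordFrequencyModel,
    period: int,
    n_diseases: int = 15,
) -> np.ndarray:
    """One query's (6 + D) feature vector.

    Layout: [Query_type, Query_len, Click_num, Position_max, Position_mean,
    Word_freq_change] ++ D-dim disease multi-hot.  Position statistics are 0
    when nothing was clicked.
    """
    positions = [pos for _, pos in record.clicks]
    vec = np.zeros(_N_QUERY_STATS + n_diseases)
    vec[0] = annotation.matched_level
    vec[1] = len(record.tokens)
    vec[2] = len(record.clicks)
    vec[3] = max(positions) if positions else 0.0
    vec[4] = float(np.mean(positions)) if positions else 0.0
    vec[5] = wf_model.query_change(record.tokens, period)
    for d in annotation.disease_hits:
        if 1 <= d <= n_diseases:
            vec[_N_QUERY_STATS + d - 1] = 1.0
    return vec


# ---------------------------------------------------------------------------
# per-session features


def session_features(
    session: Session,
    query_sequence: np.ndarray,
    vocab: SemanticVocabulary,
) -> np.ndarray:
    """The 38-dim session vector from a session and its query sequence.

    The 8 statistics are [Session_len, Key_num, Q2_num, Q3_num,
    Sum_click_num, All_position_max, All_position_mean,
    All_word_freq_change]; All_position_mean averages Position_mean over
    queries that have at least one click (0 when no query was clicked).
    The 30 semantic bits flag presence of each vocabulary word in any query
    and each vocabulary domain in any click.
    """
    if len(session) == 0:
        raise ValueError("empty session")
    if len(query_sequence) != len(session):
        raise ValueError("query_sequence length must equal session length")
    levels = query_sequence[:, 0]
    clicks = query_sequence[:, 2]
    pos_max = query_sequence[:, 3]
    pos_mean = query_sequence[:, 4]
    wfc = query_sequence[:, 5]

    vec = np.zeros(N_SESSION_FEATURES)
    vec[0] = len(session)
    vec[1] = int(np.sum(levels == 1))
    vec[2] = int(np.sum(levels == 2))
    vec[3] = int(np.sum(levels == 3))
    vec[4] = clicks.sum()
    vec[5] = pos_max.max()
    clicked = clicks > 0
    vec[6] = float(pos_mean[clicked].mean()) if clicked.any() else 0.0
    vec[7] = float(wfc.mean())

    text = " ".join(" ".join(r.tokens) for r in session.records)
    domains = {dom for r in session.records for dom, _ in r.clicks}
    for i, w in enumerate(vocab.words):
        if w in text:
            vec[8 + i] = 1.0
    off = 8 + len(vocab.words)
    for i, dom in enumerate(vocab.url_domains):
        if dom in domains:
            vec[off + i] = 1.0
    return vec


# ---------------------------------------------------------------------------
# semantic vocabulary selection


def _class_frequencies(
    sessions: Sequence[Session], labels: Sequence, extract
) -> tuple[list[dict[str, float]], list[int]]:
    """Per-class fraction of sessions containing each item."""
    counts: list[dict[str, int]] = [{}, {}, {}]
    sizes = [0, 0, 0]
    for s, lab in zip(sessions, labels):
        c = as_intent_index(lab)
        sizes[c] += 1
        for item in set(extract(s)):
            counts[c][item] = counts[c].get(item, 0) + 1
    for c, name in enumerate(INTENT_NAMES):
        if sizes[c] == 0:
            raise ValueError(f"no labeled sessions for intent class {name}")
    freqs = [
        {w: n / sizes[c] for w, n in counts[c].items()} for c in range(3)
    ]
    return freqs, sizes


def _select_top(freqs: list[dict[str, float]], top_k: int) -> list[str]:
    """Top-k items per class by specificity, each item assigned to its
    argmax class; returns the 3*top_k list ordered RD, NEWS, OTHER."""
    items = sorted(set().union(*freqs))
    spec = {}
    for w in items:
        f = [freqs[c].get(w, 0.0) for c in range(3)]
        s = [f[c] / (1.0 + max(f[c2] for c2 in range(3) if c2 != c)) for c in range(3)]
        best = int(np.argmax(s))  # ties -> lowest class index
        spec[w] = (best, s[best])
    chosen: list[str] = []
    for c in range(3):
        candidates = sorted(
            (w for w in items if spec[w][0] == c),
            key=lambda w: (-spec[w][1], w),
        )
        if len(candidates) < top_k:
            raise ValueError(
                f"class {INTENT_NAMES[c]} has only {len(candidates)} specific "
                f"items; need {top_k}"
            )
        chosen.extend(candidates[:top_k])
    return chosen


def select_semantic_vocabulary(
    sessions: Sequence[Session],
    labels: Sequence,
    top_k: int = 5,
) -> SemanticVocabulary:
    """Pick the intent-specific words and URL domains from labeled sessions.

    For each candidate item and class, specificity = freq(item, class) /
    (1 + max freq in the other classes), frequencies being the fraction of
    the class's sessions containing the item.  Each item is assigned to its
    argmax class; the top ``top_k`` per class are kept, ties broken
    lexicographically.
    """
    word_freqs, _ = _class_frequencies(
        sessions, labels, lambda s: (t for r in s.records for t in r.tokens)
    )
    dom_freqs, _ = _class_frequencies(
        sessions, labels, lambda s: (d for r in s.records for d, _ in r.clicks)
    )
    return SemanticVocabulary(
        words=tuple(_select_top(word_freqs, top_k)),
        url_domains=tuple(_select_top(dom_freqs, top_k)),
    )


# ---------------------------------------------------------------------------
# sklearn-style transformer


class SessionFeaturizer(TransformerMixin, BaseEstimator):
    """Transform sessions into (session vector, query sequence) features.

    ``fit`` learns the word-frequency model from a corpus of sessions (all
    of Session Set S, not only labeled ones) and the semantic vocabulary
    from the labeled sessions passed as ``X``/``y``; ``transform`` emits
    :class:`SessionFeatures` per session.

    Parameters
    ----------
    n_diseases : width of the query-level disease multi-hot.
    n_periods : number of seasons for the word-frequency model.
    alpha : smoothing constant of the change statistic.
    top_k : vocabulary size per intent class (5 gives the 38-dim vector).
    """

    def __init__(
        self,
        n_diseases: int = 15,
        n_periods: int = 16,
        alpha: float = 1.0,
        top_k: int = 5,
    ):
        self.n_diseases = n_diseases
        self.n_periods = n_periods
        self.alpha = alpha
        self.top_k = top_k

    def fit(self, X: Sequence[Session], y: Sequence, corpus: Iterable[Session] | None = None):
        """Fit on labeled sessions ``X`` with intent labels ``y``.

        ``corpus`` optionally supplies the full session set for the
        word-frequency counts; it defaults to ``X``.
        """
        self.wf_model_ = WordFrequencyModel.fit(
            list(corpus) if corpus is not None else list(X),
            n_periods=self.n_periods,
            alpha=self.alpha,
        )
        self.vocabulary_ = select_semantic_vocabulary(X, y, top_k=self.top_k)
        return self

    def transform(self, X: Sequence[Session]) -> list[SessionFeatures]:
        feats = []
        for s in X:
            if s.period_id is None:
                raise ValueError("sessions must carry period_id")
            if not s.annotations:
                raise ValueError("sessions must be annotated (pass a lexicon "
                                 "to build_sessions)")
            seq = np.stack(
                [
                    query_features(
                        r, a, self.wf_model_, s.period_id, self.n_diseases
                    )
                    for r, a in zip(s.records, s.annotations)
                ]
            )
            feats.append(
                SessionFeatures(
                    session_vector=session_features(s, seq, self.vocabulary_),
                    query_sequence=seq,
                )
            )
        return feats
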