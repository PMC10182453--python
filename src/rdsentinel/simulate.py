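"""Synthetic query-log world: lexicon, incidences, sessions, news bursts.

Real search logs and the clinical rare-disease registry are proprietary,
so this module generates a complete synthetic study world whose ground
truth is known exactly, making every stage of the pipeline testable:

* a three-level keyword lexicon over D diseases (names, genes, treatments
  at level 1; symptoms and pleiotropic treatments at level 2; a shared
  general-medical pool at level 3);
* per-(disease, region, season) session counts by intent — RD-concerned,
  news-concerned, other — around a 24% / 6.5% / 69% mixture, with
  region weights mirroring a population gradient (East > West ~ Central >
  Northeast) and per-disease seasonal cycles;
* news *burst events* that multiply news-session volume for one disease
  in one season and plant a season-specific burst word;
* true incidences linearly linked to the session counts through rank-1
  (disease x region) coefficient products — positive for RD sessions and
  mostly negative for news sessions — plus truncated Gaussian noise, so
  the factorized estimator's model class contains the generating process;
* realized query logs: each session becomes 1-8 query records with
  intra-session gaps under 30 minutes and inter-session gaps over 30
  minutes, class-dependent vocabulary, click domains and click positions.

Token strings are synthetic Latin identifiers; the pipeline is
script-agnostic, so nothing depends on the language of real queries.
All randomness flows from a single seed; regeneration is byte-identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .intent_labels import NEWS, OTHER, RD
from .lexicon import KeywordEntry, Lexicon
from .sessions import LogRecord, Session, StudyWindow, build_sessions

__all__ = [
    "NewsEvent",
    "WorldConfig",
    "PanelCoefficients",
    "GroundTruth",
    "SyntheticWorld",
    "generate_lexicon",
    "generate_panel",
    "generate_world",
    "burst_word",
]

_CATEGORY_PROBS = (0.951, 0.018, 0.031)  # name / gene / treatment query mix


@dataclass(frozen=True)
class NewsEvent:
    """A burst of news interest in one disease during one season."""

    disease_id: int
    period: int
    multiplier: float

    def __post_init__(self):
        if self.multiplier < 1:
            raise ValueError("burst multiplier must be >= 1")


_DEFAULT_EVENTS = (
    NewsEvent(3, 4, 5.0),
    NewsEvent(5, 9, 5.0),   # well-known disease, burst in the validation year
    NewsEvent(1, 10, 5.0),
    NewsEvent(1, 14, 5.0),  # recurring annual burst, test year
    NewsEvent(5, 15, 5.0),
)


@dataclass(frozen=True)
class WorldConfig:
    """Study-world dimensions and generating conditions.

    Defaults mirror the study frame: 15 diseases x 4 regions x 16 seasons
    (2016-2019), an intent mixture of 24% RD / 6.5% news / 69.5% other,
    and region weights proportional to a realistic population gradient.
    ``noise_frac`` scales observation noise to the mean incidence.
    """

    n_diseases: int = 15
    n_regions: int = 4
    n_periods: int = 16
    n_users: int = 4000
    sessions_per_user: float = 1.282
    mixture: tuple[float, float, float] = (0.24, 0.065, 0.695)
    region_weights: tuple[float, ...] = (0.384, 0.271, 0.265, 0.078)
    seasonal_amplitude: float = 0.3
    disease_spread: float = 0.6
    other_jitter_sd: float = 0.3
    news_events: tuple[NewsEvent, ...] = _DEFAULT_EVENTS
    positive_news_diseases: tuple[int, ...] = (1, 6)
    noise_frac: float = 0.05
    extra_key_prob: float = 0.2
    start_year: int = 2016
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.mixture) - 1.0) > 1e-9:
            raise ValueError("intent mixture must sum to 1")
        if min(self.n_diseases, self.n_regions, self.n_periods, self.n_users) < 1:
            raise ValueError("all dimensions must be >= 1")
        if len(self.region_weights) != self.n_regions:
            raise ValueError("need one region weight per region")
        for ev in self.news_events:
            if not 1 <= ev.disease_id <= self.n_diseases:
                raise ValueError(f"news event disease {ev.disease_id} out of range")
            if not 1 <= ev.period <= self.n_periods:
                raise ValueError(f"news event period {ev.period} out of range")

    @property
    def window(self) -> StudyWindow:
        return StudyWindow(start_year=self.start_year, n_periods=self.n_periods)

    @property
    def expected_sessions(self) -> float:
        return self.n_users * self.sessions_per_user


@dataclass(frozen=True)
class PanelCoefficients:
    """Rank-1 generating coefficients of the incidence model."""

    alpha_d: np.ndarray
    theta_d: np.ndarray
    alpha_n: np.ndarray
    theta_n: np.ndarray
    beta: np.ndarray
    phi: np.ndarray

    def predict(self, d_idx, r_idx, x_sd, x_sn) -> np.ndarray:
        """Noise-free incidence for 0-based disease/region index arrays."""
        return (
            self.alpha_d[d_idx] * self.theta_d[r_idx] * x_sd
            + self.alpha_n[d_idx] * self.theta_n[r_idx] * x_sn
            + self.beta[d_idx] * self.phi[r_idx]
        )


def burst_word(disease_id: int, period: int) -> str:
    """The season-specific token planted in a news burst's queries."""
    return f"burst{disease_id:02d}p{period:02d}"


# ---------------------------------------------------------------------------
# lexicon


def generate_lexicon(config: WorldConfig) -> Lexicon:
    """Synthetic three-level lexicon: per disease one name, gene and
    treatment (level 1), three symptoms plus one pleiotropic treatment
    (level 2), and a shared 20-term general-medical pool (level 3)."""
    entries = []
    for i in range(1, config.n_diseases + 1):
        entries.append(KeywordEntry(f"d{i:02d}name0", 1, i, "name"))
        entries.append(KeywordEntry(f"d{i:02d}gene0", 1, i, "gene"))
        entries.append(KeywordEntry(f"d{i:02d}treat0", 1, i, "treatment"))
        for s in range(3):
            entries.append(KeywordEntry(f"d{i:02d}sym{s}", 2, i, "symptom"))
        entries.append(KeywordEntry(f"d{i:02d}ptx0", 2, i, "pleiotropic_treatment"))
    for t in range(20):
        entries.append(KeywordEntry(f"med{t:02d}", 3))
    return Lexicon(entries)


# ---------------------------------------------------------------------------
# panel (counts + incidence)


def _cell_weights(config: WorldConfig, rng: np.random.Generator):
    D, R, T = config.n_diseases, config.n_regions, config.n_periods
    disease_w = np.exp(rng.normal(0.0, config.disease_spread, size=D))
    disease_w /= disease_w.sum()
    phase = rng.uniform(0.0, 2 * np.pi, size=D)
    k = np.arange(T)
    season = 1.0 + config.seasonal_amplitude * np.sin(
        2 * np.pi * k[None, :] / 4 + phase[:, None]
    )  # (D, T)
    w = (
        disease_w[:, None, None]
        * np.asarray(config.region_weights)[None, :, None]
        * season[:, None, :]
    )
    return w / w.sum()


def _generate_coefficients(
    config: WorldConfig, rng: np.random.Generator
) -> PanelCoefficients:
    D, R, T = config.n_diseases, config.n_regions, config.n_periods
    mean_x_rd = config.mixture[0] * config.expected_sessions / (D * R * T)
    base = 1e-6 / max(mean_x_rd, 1e-9)  # incidences live at the 1e-6 scale
    sign = np.where(
        np.isin(np.arange(1, D + 1), config.positive_news_diseases), 1.0, -1.0
    )
    magnitude = np.where(
        sign > 0,
        rng.uniform(0.005, 0.02, size=D),
        rng.uniform(0.05, 0.15, size=D),
    )
    return PanelCoefficients(
        alpha_d=rng.uniform(0.8, 1.2, size=D) * base,
        theta_d=rng.uniform(0.7, 1.3, size=R),
        alpha_n=sign * magnitude * base,
        theta_n=rng.uniform(0.7, 1.3, size=R),
        beta=rng.uniform(0.1, 0.3, size=D) * 1e-6,
        phi=rng.uniform(0.8, 1.2, size=R),
    )


def generate_panel(
    config: WorldConfig,
    rng: np.random.Generator | None = None,
    coeffs: PanelCoefficients | None = None,
) -> tuple[pd.DataFrame, PanelCoefficients]:
    """Draw per-cell session counts by intent, query counts, and incidence.

    Returns a complete (disease, region, period) grid with columns x_sd,
    x_sn, x_other, x_name, x_gene, x_treat and y (true incidence, unscaled).
    The query counts mix level-1 queries from sessions of *all* intents —
    which is precisely why the raw query signal is contaminated by news
    bursts and off-target search volume.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    D, R, T = config.n_diseases, config.n_regions, config.n_periods
    w = _cell_weights(config, rng)
    if coeffs is None:
        coeffs = _generate_coefficients(config, rng)
    total = config.expected_sessions
    p_rd, p_news, p_other = config.mixture

    lam_news = p_news * total * w
    for ev in config.news_events:
        lam_news[ev.disease_id - 1, :, ev.period - 1] *= ev.multiplier
    jitter = np.exp(
        rng.normal(-config.other_jitter_sd**2 / 2, config.other_jitter_sd, size=w.shape)
    )
    x_sd = rng.poisson(p_rd * total * w)
    x_sn = rng.poisson(lam_news)
    x_other = rng.poisson(p_other * total * w * jitter)

    n_sessions = x_sd + x_sn + x_other
    keys = n_sessions + rng.binomial(n_sessions, config.extra_key_prob)
    flat_keys = keys.ravel()
    cats = np.stack(
        [rng.multinomial(k, _CATEGORY_PROBS) for k in flat_keys]
    ).reshape(D, R, T, 3)

    d_idx, r_idx, _ = np.meshgrid(
        np.arange(D), np.arange(R), np.arange(T), indexing="ij"
    )
    y_det = coeffs.predict(d_idx, r_idx, x_sd, x_sn)
    noise_sd = config.noise_frac * max(y_det.mean(), 0.0)
    y = np.maximum(y_det + rng.normal(0.0, noise_sd, size=y_det.shape), 0.0)

    k_idx = np.meshgrid(np.arange(D), np.arange(R), np.arange(T), indexing="ij")[2]
    panel = pd.DataFrame(
        {
            "disease": d_idx.ravel() + 1,
            "region": r_idx.ravel() + 1,
            "period": k_idx.ravel() + 1,
            "x_sd": x_sd.ravel(),
            "x_sn": x_sn.ravel(),
            "x_other": x_other.ravel(),
            "x_name": cats[..., 0].ravel(),
            "x_gene": cats[..., 1].ravel(),
            "x_treat": cats[..., 2].ravel(),
            "y": y.ravel(),
        }
    )
    return panel, coeffs


# ---------------------------------------------------------------------------
# log realization


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must rediscover."""

    coeffs: PanelCoefficients
    panel: pd.DataFrame
    session_intents: list[int]
    session_record_ids: list[list[int]]
    key_record_ids: set[int]
    session_of_record: np.ndarray  # generated-session index per record

    def intent_of(self, session: Session) -> int:
        """Oracle intent of a pipeline-built session (by its first record)."""
        return self.session_intents[int(self.session_of_record[session.record_ids[0]])]


@dataclass
class SyntheticWorld:
    config: WorldConfig
    lexicon: Lexicon
    records: list[LogRecord]
    truth: GroundTruth

    @property
    def window(self) -> StudyWindow:
        return self.config.window

    @property
    def incidence(self) -> pd.DataFrame:
        return self.truth.panel[["disease", "region", "period", "y"]].rename(
            columns={"y": "incidence"}
        )

    def build_sessions(self) -> list[Session]:
        """Run the real sessionizer over the generated logs."""
        return build_sessions(
            self.records,
            self.truth.key_record_ids,
            lexicon=self.lexicon,
            window=self.window,
        )

    def oracle_intents(self, sessions: Sequence[Session]) -> list[int]:
        return [self.truth.intent_of(s) for s in sessions]


_SESSION_LEN = {RD: (3, 8), NEWS: (2, 5), OTHER: (1, 3)}
_CLICK_PROB = {RD: 0.8, NEWS: 0.7, OTHER: 0.35}
_CLICK_POS_MAX = {RD: 3, NEWS: 5, OTHER: 10}
_DOMAINS = {
    RD: [f"clinic{n}.example" for n in range(5)],
    NEWS: [f"news{n}.example" for n in range(5)],
    OTHER: [f"portal{n}.example" for n in range(5)],
}
_CLASS_WORDS = {
    RD: [f"rdcare{n}" for n in range(5)],
    NEWS: [f"newsflash{n}" for n in range(5)],
    OTHER: [f"chatter{n}" for n in range(5)],
}
_LEVEL1_SUFFIX = ("name0", "gene0", "treat0")


def _session_queries(intent, disease, period, burst_periods, extra_key_prob, rng):
    """Token lists for one session; returns (queries, key query categories)."""
    lo, hi = _SESSION_LEN[intent]
    length = int(rng.integers(lo, hi + 1))
    key_pos = {int(rng.integers(0, length))}
    if length > 1 and rng.random() < extra_key_prob:
        extra = int(rng.integers(0, length))
        key_pos.add(extra)
    queries = []
    key_categories = []
    for q in range(length):
        tokens = []
        if q in key_pos:
            cat = int(rng.choice(3, p=_CATEGORY_PROBS))
            key_categories.append(cat)
            tokens.append(f"d{disease:02d}{_LEVEL1_SUFFIX[cat]}")
        if intent == RD:
            if rng.random() < 0.6:
                tokens.append(f"d{disease:02d}sym{int(rng.integers(0, 3))}")
            if rng.random() < 0.6:
                tokens.append(f"med{int(rng.integers(0, 20))}")
            if rng.random() < 0.6:
                tokens.append(_CLASS_WORDS[RD][int(rng.integers(0, 5))])
        elif intent == NEWS:
            tokens.append(_CLASS_WORDS[NEWS][int(rng.integers(0, 5))])
            if (disease, period) in burst_periods:
                tokens.append(burst_word(disease, period))
            if rng.random() < 0.2:
                tokens.append(f"med{int(rng.integers(0, 20))}")
        else:
            tokens.append(_CLASS_WORDS[OTHER][int(rng.integers(0, 5))])
            if rng.random() < 0.5:
                tokens.append(f"misc{int(rng.integers(0, 20))}")
        queries.append(tokens)
    return queries, key_categories


def _session_clicks(intent, n_queries, rng):
    clicks = []
    for _ in range(n_queries):
        if rng.random() < _CLICK_PROB[intent]:
            n = 1 + int(rng.random() < 0.3)
            qc = tuple(
                (
                    _DOMAINS[intent][int(rng.integers(0, 5))],
                    int(rng.integers(1, _CLICK_POS_MAX[intent] + 1)),
                )
                for _ in range(n)
            )
        else:
            qc = ()
        clicks.append(qc)
    return clicks


def generate_world(config: WorldConfig) -> SyntheticWorld:
    """Generate the full world: panel plus realized, fully-labeled logs.

    The realized logs aggregate back to exactly the panel's per-cell
    session counts, and the generated session boundaries are recoverable
    by the 30-minute gap rule (intra-session gaps are 10 s - 15 min;
    same-user sessions sit more than 30 minutes apart).
    """
    rng = np.random.default_rng(config.seed)
    lexicon = generate_lexicon(config)
    panel, coeffs = generate_panel(config, rng=rng)
    window = config.window
    burst_periods = {(ev.disease_id, ev.period) for ev in config.news_events}

    # session blueprint per cell and intent, in deterministic order
    specs: list[tuple[int, int, int, int]] = []  # (intent, disease, region, period)
    for row in panel.itertuples(index=False):
        for intent, count in ((RD, row.x_sd), (NEWS, row.x_sn), (OTHER, row.x_other)):
            specs.extend(
                (intent, row.disease, row.region, row.period) for _ in range(count)
            )

    # assign sessions to users within each region; most users search once
    user_counter = 0
    user_sessions: list[tuple[str, list[int]]] = []
    by_region: dict[int, list[int]] = {}
    for idx, spec in enumerate(specs):
        by_region.setdefault(spec[2], []).append(idx)
    count_probs = np.array([0.86, 0.09, 0.03, 0.02])
    for region in sorted(by_region):
        idxs = by_region[region]
        order = rng.permutation(len(idxs))
        pos = 0
        while pos < len(idxs):
            take = 1 + int(rng.choice(4, p=count_probs))
            chunk = [idxs[i] for i in order[pos : pos + take]]
            pos += take
            user_sessions.append((f"u{user_counter:07d}", chunk))
            user_counter += 1

    records: list[tuple[str, int, int, tuple, tuple, int]] = []
    session_intents = [s[0] for s in specs]
    key_tally = np.zeros(
        (3, config.n_diseases, config.n_regions, config.n_periods), dtype=int
    )
    for user_id, session_idxs in user_sessions:
        # order the user's sessions by period so times increase
        session_idxs = sorted(session_idxs, key=lambda i: specs[i][3])
        prev_end = -math.inf
        for s_idx in session_idxs:
            intent, disease, region, period = specs[s_idx]
            p_start, p_end = window.period_bounds(period)
            queries, key_cats = _session_queries(
                intent, disease, period, burst_periods, config.extra_key_prob, rng
            )
            for cat in key_cats:
                key_tally[cat, disease - 1, region - 1, period - 1] += 1
            clicks = _session_clicks(intent, len(queries), rng)
            start = float(
                rng.uniform(p_start + 43200, p_end - 43200)
            )
            if start <= prev_end + 1801:
                start = prev_end + 1801 + float(rng.uniform(0, 3600))
            t = int(start)
            for tokens, qc in zip(queries, clicks):
                records.append((user_id, t, region, tuple(tokens), qc, s_idx))
                t += int(rng.integers(10, 900))
            prev_end = t

    records.sort(key=lambda r: (r[0], r[1]))
    log_records = [
        LogRecord(user_id=u, timestamp=float(t), region_id=reg, tokens=tok, clicks=c)
        for u, t, reg, tok, c, _ in records
    ]
    session_of_record = np.array([r[5] for r in records])
    session_record_ids: list[list[int]] = [[] for _ in specs]
    for rec_id, r in enumerate(records):
        session_record_ids[r[5]].append(rec_id)
    level1 = {e.text for e in lexicon if e.level == 1}
    key_record_ids = {
        i for i, r in enumerate(records) if any(tok in level1 for tok in r[3])
    }
    # make the panel's query side consistent with the realized logs
    panel = panel.copy()
    for m, col in enumerate(("x_name", "x_gene", "x_treat")):
        panel[col] = key_tally[m].ravel()
    truth = GroundTruth(
        coeffs=coeffs,
        panel=panel,
        session_intents=session_intents,
        session_record_ids=session_record_ids,
        key_record_ids=key_record_ids,
        session_of_record=session_of_record,
    )
    return SyntheticWorld(
        config=config, lexicon=lexicon, records=log_records, truth=truth
    )
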